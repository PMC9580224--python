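"""Approach I: grid search over connectivity-kernel parameters with
category-balanced cross-validation.

Kernel Jacobians over full images are translation invariant, so distances
inside the sweeps run through the convolutional path: a batched FFT engine
correlates every pair's difference image with every candidate stencil and
sums the squared response over the grid (exactly the dense quadratic form
with matched truncation, never materializing a D x D matrix).

Selection follows the mean-of-fold-argmin rule: each fold contributes the
parameter value of its minimum error (1 - Pearson with DMOS), the fold
argmins are averaged and rounded to the grid step.  Ties within a fold go to
the smallest parameter (prefer the narrower kernel).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sfft

from .approach2 import TrainingSet
from .evalstats import pearson
from .kernels import DOGParams, GaussianParams, build_stencil

__all__ = [
    "SweepGrid",
    "FoldPlan",
    "make_folds",
    "SweepResult",
    "sweep_gaussian",
    "sweep_dog",
    "alpha_marginal",
]


def _grid(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step)) + 1
    return tuple(round(lo + k * step, 10) for k in range(n))


@dataclass(frozen=True)
class SweepGrid:
    """Parameter grids for the Gaussian and DOG sweeps (pixel units).

    Defaults: Gaussian sigma in [0.4, 3.0] by 0.1; DOG center in [0.6, 5.0]
    and surround in [0.6, 5.6], both by 0.2; alpha in [0.5, 1.5] by 0.1.
    Only surround > center combinations are admissible.
    """

    sigma_values: tuple[float, ...] = _grid(0.4, 3.0, 0.1)
    dog_center_values: tuple[float, ...] = _grid(0.6, 5.0, 0.2)
    dog_surround_values: tuple[float, ...] = _grid(0.6, 5.6, 0.2)
    alpha_values: tuple[float, ...] = _grid(0.5, 1.5, 0.1)

    def __post_init__(self) -> None:
        for name in ("sigma_values", "dog_center_values",
                     "dog_surround_values", "alpha_values"):
            vals = getattr(self, name)
            if len(vals) == 0 or any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be nonempty and ascending")

    def dog_combos(self) -> list[tuple[float, float, float]]:
        """All (center, surround, alpha) with surround > center."""
        return [
            (sc, ss, a)
            for sc, ss in itertools.product(self.dog_center_values,
                                            self.dog_surround_values)
            if ss > sc
            for a in self.alpha_values
        ]


@dataclass(frozen=True)
class FoldPlan:
    """Partition of reference images into folds, balanced within category."""

    assignment: dict = field(hash=False)
    n_folds: int = 0

    def fold_of(self, reference_id: str) -> int:
        return self.assignment[reference_id]

    def members(self, fold: int) -> list[str]:
        return [r for r, f in self.assignment.items() if f == fold]


def make_folds(reference_ids, categories, n_folds: int, seed: int | None = None) -> FoldPlan:
    """Random category-balanced fold assignment of reference images.

    Within each category the references are shuffled and dealt round-robin,
    so per-category fold counts differ by at most one (equal when counts
    divide).  All degraded versions of a reference inherit its fold.
    Deterministic under ``seed``.
    """
    reference_ids = list(reference_ids)
    categories = list(categories)
    if len(reference_ids) != len(categories):
        raise ValueError("one category per reference required")
    if len(set(reference_ids)) < n_folds:
        raise ValueError("fewer references than folds")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    by_cat: dict[str, list[str]] = {}
    for rid, cat in zip(reference_ids, categories):
        by_cat.setdefault(cat, []).append(rid)
    for cat in sorted(by_cat):
        members = sorted(set(by_cat[cat]))
        rng.shuffle(members)
        for pos, rid in enumerate(members):
            assignment[rid] = pos % n_folds
    return FoldPlan(assignment=assignment, n_folds=n_folds)


def _batch_stencil_distances(
    pairs, stencils: list[np.ndarray], radius: int
) -> np.ndarray:
    """(n_pairs, n_stencils) squared convolutional distances via FFT.

    Every stencil is zero-embedded into a common (2*radius+1) support so one
    set of padded difference-image FFTs serves the whole sweep.
    """
    H, W = pairs[0][0].shape
    shape = (H + 2 * radius, W + 2 * radius)
    diffs = np.stack([np.asarray(b, float) - np.asarray(a, float) for a, b in pairs])
    dhat = sfft.rfft2(diffs, s=shape, axes=(1, 2))
    out = np.empty((len(pairs), len(stencils)))
    for k, S in enumerate(stencils):
        K = np.zeros((2 * radius + 1, 2 * radius + 1))
        r0 = radius - S.shape[0] // 2
        K[r0 : r0 + S.shape[0], r0 : r0 + S.shape[1]] = S
        khat = sfft.rfft2(K, s=shape)
        resp = sfft.irfft2(dhat * khat, s=shape, axes=(1, 2))
        crop = resp[:, radius : radius + H, radius : radius + W]
        out[:, k] = np.sum(crop**2, axis=(1, 2))
    return out


@dataclass
class SweepResult:
    """Per-fold error table plus the selected parameters.

    ``table`` has one row per (fold, parameter combination) with columns
    ``pearson_linear``, ``pearson_loglog`` and ``error`` (1 - Pearson on the
    selection axes); ``selected`` is the mean-of-argmin choice.
    """

    table: pd.DataFrame
    selected: dict
    per_fold_argmin: list[dict]


def _fold_indices(train: TrainingSet, folds: FoldPlan) -> dict[int, np.ndarray]:
    if train.reference_ids is None:
        raise ValueError("sweeps need TrainingSet.reference_ids for folding")
    fold_of = np.array([folds.fold_of(r) for r in train.reference_ids])
    return {f: np.flatnonzero(fold_of == f) for f in range(folds.n_folds)}


def _round_to_step(value: float, step: float) -> float:
    return round(round(value / step) * step, 10)


def _sweep(
    train: TrainingSet,
    folds: FoldPlan,
    param_rows: list[dict],
    stencils: list[np.ndarray],
    radius: int,
    axes: str,
) -> tuple[pd.DataFrame, list[int]]:
    distances = _batch_stencil_distances(train.pairs, stencils, radius)
    rows = []
    argmins: list[int] = []
    idx = _fold_indices(train, folds)
    for f in range(folds.n_folds):
        sel = idx[f]
        if sel.size < 3:
            raise ValueError(f"fold {f} has fewer than 3 pairs")
        errs = np.empty(len(param_rows))
        for k, params in enumerate(param_rows):
            scores = distances[sel, k]
            r_lin = pearson(scores, train.dmos[sel], axes="linear")
            r_log = pearson(scores, train.dmos[sel], axes="loglog")
            err = 1.0 - (r_log if axes == "loglog" else r_lin)
            errs[k] = err
            rows.append({"fold": f, **params, "pearson_linear": r_lin,
                         "pearson_loglog": r_log, "error": err})
        argmins.append(int(np.argmin(errs)))  # first minimum = smallest params
    return pd.DataFrame(rows), argmins


def sweep_gaussian(
    train: TrainingSet,
    grid: SweepGrid = SweepGrid(),
    folds: FoldPlan | None = None,
    n_folds: int = 5,
    seed: int | None = None,
    axes: str = "linear",
) -> SweepResult:
    """Evaluate every Gaussian sigma on every fold and select one.

    Selected sigma = mean of the per-fold minimum-error sigmas, rounded to
    the 0.1 px grid step.
    """
    if folds is None:
        folds = make_folds(train.reference_ids, train.categories or
                           ["all"] * len(train.pairs), n_folds, seed)
    sigmas = grid.sigma_values
    radius = max(1, math.ceil(4.0 * max(sigmas)))
    stencils = [build_stencil(GaussianParams(s), truncation_radius=radius)
                for s in sigmas]
    params = [{"sigma": s} for s in sigmas]
    table, argmins = _sweep(train, folds, params, stencils, radius, axes)
    fold_sigmas = [sigmas[k] for k in argmins]
    step = round(sigmas[1] - sigmas[0], 10) if len(sigmas) > 1 else 0.1
    selected = {"sigma": _round_to_step(float(np.mean(fold_sigmas)), step)}
    return SweepResult(table, selected, [{"sigma": s} for s in fold_sigmas])


def sweep_dog(
    train: TrainingSet,
    grid: SweepGrid = SweepGrid(),
    folds: FoldPlan | None = None,
    n_folds: int = 5,
    seed: int | None = None,
    axes: str = "linear",
) -> SweepResult:
    """Evaluate every admissible (center, surround, alpha) on every fold.

    Selection averages each parameter of the per-fold argmin triples and
    rounds to its grid step.
    """
    if folds is None:
        folds = make_folds(train.reference_ids, train.categories or
                           ["all"] * len(train.pairs), n_folds, seed)
    combos = grid.dog_combos()
    radius = max(1, math.ceil(4.0 * max(grid.dog_surround_values)))
    stencils = [
        build_stencil(DOGParams(sc, ss, a), truncation_radius=radius)
        for sc, ss, a in combos
    ]
    params = [{"sigma_center": sc, "sigma_surround": ss, "alpha": a}
              for sc, ss, a in combos]
    table, argmins = _sweep(train, folds, params, stencils, radius, axes)
    fold_best = [combos[k] for k in argmins]
    steps = (
        round(grid.dog_center_values[1] - grid.dog_center_values[0], 10),
        round(grid.dog_surround_values[1] - grid.dog_surround_values[0], 10),
        round(grid.alpha_values[1] - grid.alpha_values[0], 10),
    )
    means = np.mean(np.array(fold_best), axis=0)
    selected = {
        "sigma_center": _round_to_step(float(means[0]), steps[0]),
        "sigma_surround": _round_to_step(float(means[1]), steps[1]),
        "alpha": _round_to_step(float(means[2]), steps[2]),
    }
    return SweepResult(
        table,
        selected,
        [{"sigma_center": sc, "sigma_surround": ss, "alpha": a}
         for sc, ss, a in fold_best],
    )


def alpha_marginal(table: pd.DataFrame) -> pd.DataFrame:
    """2D (center, surround) error surface with alpha eliminated.

    For each fold and (sigma_center, sigma_surround) cell, keeps the row
    with the best (lowest) error over alpha — the surface used for visual
    reporting of DOG sweeps.
    """
    key = ["fold", "sigma_center", "sigma_surround"]
    idx = table.groupby(key)["error"].idxmin()
    return table.loc[idx].reset_index(drop=True)
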
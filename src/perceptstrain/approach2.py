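"""Approach II: random-walk coordinate descent on a 64x64 tile Jacobian.

The regression searches the space of symmetric, unit-diagonal tile operators
for the one whose tiled distances correlate maximally with human DMOS.  Each
iteration perturbs one randomly chosen lower-triangle cell by +/- step
(mirrored to the upper triangle), keeps the better of the two candidates if
it reduces ``1 - Pearson(dmos, scores)``, and otherwise keeps the incumbent.
No regularization is applied.

Because the tiled distance is linear in the Gram matrix P^T P,

    d^2 = sum_t Delta_t^T P^T P Delta_t = <P^T P, sum_t Delta_t Delta_t^T>,

caching the per-pair tile-difference scatter matrix S = sum_t Delta_t
Delta_t^T makes one error evaluation a 64x64 product plus one inner product
per pair.  The direct tiled-distance recomputation is retained as the
independent oracle path (``cache=False``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evalstats import pearson
from .kernels import GridGeometry, Jacobian
from .metric import tile_differences, tiled_distance

__all__ = [
    "TrainingSet",
    "RegressionConfig",
    "FitResult",
    "pair_scatter",
    "evaluate_error",
    "fit_jacobian",
]


@dataclass
class TrainingSet:
    """Image pairs with their DMOS targets.

    ``pairs`` holds (reference, degraded) 2D arrays; ``dmos`` is one value
    per pair in [0, 1]; ``categories`` is optional per-pair labels.
    """

    pairs: Sequence[tuple[np.ndarray, np.ndarray]]
    dmos: np.ndarray
    categories: Sequence[str] | None = None
    reference_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.dmos = np.asarray(self.dmos, dtype=float)
        if len(self.pairs) != self.dmos.size:
            raise ValueError("one DMOS value per pair required")
        for name, seq in (("categories", self.categories),
                          ("reference_ids", self.reference_ids)):
            if seq is not None and len(seq) != len(self.pairs):
                raise ValueError(f"{name} must have one entry per pair")
        if self.dmos.size < 3:
            raise ValueError("need at least 3 pairs (Pearson undefined below)")
        if np.any((self.dmos < 0) | (self.dmos > 1)):
            raise ValueError("DMOS values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class RegressionConfig:
    """Knobs of the coordinate-descent regression.

    ``step`` is the cell increment (0.1), ``iterations`` the number of
    random-walk steps (10,000), ``bounds`` the admissible cell range
    ([-1, 1]; a candidate that would leave it is discarded, not projected),
    ``correlation_axes`` the axes on which the training Pearson is taken.
    """

    step: float = 0.1
    iterations: int = 10_000
    bounds: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0
    correlation_axes: str = "linear"
    tile: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must be ordered")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


@dataclass
class FitResult:
    """Fitted tile Jacobian with its optimization history.

    ``error_trace[k]`` is the incumbent error (1 - Pearson) after iteration
    k (index 0 is the initial, Euclidean, error); it is non-increasing.
    """

    jacobian: Jacobian
    error_trace: np.ndarray
    accepted_steps: int
    config: RegressionConfig


def pair_scatter(
    ref: np.ndarray,
    test: np.ndarray,
    tile: tuple[int, int] = (8, 8),
    edge: str = "refuse",
) -> np.ndarray:
    """Sum over tiles of the outer product of the linearized tile difference.

    Symmetric PSD matrix of size (th*tw, th*tw); the tiled distance under
    any operator P is the Frobenius inner product of P^T P with it.
    """
    deltas = tile_differences(ref, test, tile=tile, edge=edge)
    return deltas.T @ deltas


def _scores_from_scatters(P: np.ndarray, scatters_flat: np.ndarray) -> np.ndarray:
    return scatters_flat @ (P.T @ P).ravel()


def _tile_scores(P: np.ndarray, train: TrainingSet, tile) -> np.ndarray:
    return np.array([tiled_distance(a, b, P, tile=tile) for a, b in train.pairs])


def evaluate_error(
    P: Jacobian | np.ndarray,
    train: TrainingSet,
    cfg: RegressionConfig = RegressionConfig(),
    cache: bool = True,
) -> float:
    """1 - Pearson(dmos, tiled distances under P) on the configured axes.

    ``cache=False`` forces the direct per-pair tiled-distance recomputation
    (the oracle path); the default builds scatter matrices once per call.
    """
    M = P.entries if isinstance(P, Jacobian) else np.asarray(P, dtype=float)
    if cache:
        flat = np.stack(
            [pair_scatter(a, b, tile=cfg.tile).ravel() for a, b in train.pairs]
        )
        scores = _scores_from_scatters(M, flat)
    else:
        scores = _tile_scores(M, train, cfg.tile)
    return 1.0 - pearson(scores, train.dmos, axes=cfg.correlation_axes)


def fit_jacobian(train: TrainingSet, cfg: RegressionConfig = RegressionConfig()) -> FitResult:
    """Random-walk coordinate descent from the identity (Euclidean) start.

    At each of ``cfg.iterations`` steps a strict-lower-triangle cell is
    drawn uniformly and the +step and -step candidates are scored; the
    better candidate replaces the incumbent only if it strictly reduces the
    error.  Ties between two equally improving candidates go to the
    decrement (bias toward weaker coupling).  Candidates outside ``bounds``
    are discarded.  Deterministic under ``cfg.seed``.
    """
    th, tw = cfg.tile
    D = th * tw
    geometry = GridGeometry(th, tw)
    scatters_flat = np.stack(
        [pair_scatter(a, b, tile=cfg.tile).ravel() for a, b in train.pairs]
    )
    dmos = train.dmos
    lo, hi = cfg.bounds

    P = np.eye(D)

    def error_of(M: np.ndarray) -> float:
        scores = _scores_from_scatters(M, scatters_flat)
        return 1.0 - pearson(scores, dmos, axes=cfg.correlation_axes)

    current = error_of(P)
    trace = np.empty(cfg.iterations + 1)
    trace[0] = current
    accepted = 0

    rng = np.random.default_rng(cfg.seed)
    rows, cols = np.tril_indices(D, k=-1)
    n_free = rows.size  # D(D-1)/2 free parameters

    for it in range(cfg.iterations):
        k = rng.integers(n_free)
        i, j = int(rows[k]), int(cols[k])
        base = P[i, j]
        best_err, best_val = current, None
        # evaluate -step second so an equal-error tie lands on the decrement
        for delta in (cfg.step, -cfg.step):
            val = base + delta
            if val < lo or val > hi:
                continue
            P[i, j] = P[j, i] = val
            err = error_of(P)
            if err < best_err or (best_val is not None and err == best_err):
                best_err, best_val = err, val
        if best_val is not None and best_err < current:
            P[i, j] = P[j, i] = best_val
            current = best_err
            accepted += 1
        else:
            P[i, j] = P[j, i] = base
        trace[it + 1] = current

    return FitResult(
        jacobian=Jacobian(P, geometry, meta={"fit": cfg}),
        error_trace=trace,
        accepted_steps=accepted,
        config=cfg,
    )
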
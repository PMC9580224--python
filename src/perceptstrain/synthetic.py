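"""Synthetic fixtures: correlated natural-scene-like images, block-transform
degradations at quality tiers, simulated observers driven by a known
ground-truth Jacobian, and SceneIQ-shaped dataset manifests.

The generators exist so that the whole pipeline — kernel sweeps, the
approach-II regression, and the evaluation statistics — is exercisable and
testable with no external image archive.  Images are spatially correlated
Gaussian noise (natural scenes have strong neighbor-pixel correlation, which
is the one statistic the connectivity kernels are sensitive to); the default
degrader quantizes 8x8 block cosine-transform coefficients with a
quality-scaled step, the same artifact family as JPEG, so the suite carries
no codec dependence.  A real JPEG path is available through Pillow.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from PIL import Image as PILImage
from scipy import fft as sfft
from scipy import ndimage

from .evalstats import dmos_from_rating

__all__ = [
    "SceneSpec",
    "ObserverModel",
    "RATINGS_COLUMNS",
    "gen_images",
    "degrade",
    "simulate_ratings",
    "build_manifest",
]

#: Shared ratings-table schema (CSV interchange).
RATINGS_COLUMNS = [
    "image_id",
    "reference_id",
    "category",
    "quality_level",
    "subject_id",
    "rating",
    "dmos",
]


@dataclass(frozen=True)
class SceneSpec:
    """Shape of a SceneIQ-style dataset.

    Defaults reproduce the published structure: 8 scene categories x 260
    originals, 256x256 pixels, four JPEG quality tiers (30/20/10/5 percent),
    five raters per degraded image, subjects in groups of 52 each rating 40
    originals (x4 tiers = 160 ratings per subject).
    """

    n_categories: int = 8
    refs_per_category: int = 260
    image_size: tuple[int, int] = (256, 256)
    quality_tiers: tuple[int, ...] = (30, 20, 10, 5)
    raters_per_image: int = 5
    group_size: int = 52
    images_per_subject: int = 40

    def __post_init__(self) -> None:
        if min(self.n_categories, self.refs_per_category, self.raters_per_image) < 1:
            raise ValueError("counts must be positive")
        if list(self.quality_tiers) != sorted(self.quality_tiers, reverse=True):
            raise ValueError("quality tiers must be descending")
        if self.group_size * self.images_per_subject != self.n_originals:
            raise ValueError(
                "group_size * images_per_subject must equal the number of "
                f"originals ({self.n_originals}); got "
                f"{self.group_size} * {self.images_per_subject}"
            )

    @property
    def n_originals(self) -> int:
        return self.n_categories * self.refs_per_category

    @property
    def n_degraded(self) -> int:
        return self.n_originals * len(self.quality_tiers)

    @property
    def n_rating_slots(self) -> int:
        return self.n_degraded * self.raters_per_image


def gen_images(
    n: int,
    size: tuple[int, int] = (64, 64),
    correlation_scale: float = 2.0,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Spatially correlated luminance fields, stretched to [0, 255].

    White Gaussian noise filtered by an isotropic Gaussian of
    ``correlation_scale`` pixels; scale 0 leaves the noise unfiltered.
    Deterministic under ``seed``.
    """
    if size[0] < 8 or size[1] < 8:
        raise ValueError("images must be at least one 8x8 tile")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        img = rng.standard_normal(size)
        if correlation_scale > 0:
            img = ndimage.gaussian_filter(img, correlation_scale, mode="reflect")
        lo, hi = img.min(), img.max()
        out.append((img - lo) / (hi - lo) * 255.0)
    return out


# quantization step per unit inverse quality; tier 30 -> step 80, tier 5 -> 480
# on orthonormal block-DCT coefficients of 0..255 luminance
_QUANT_BASE = 2400.0


def degrade(img: np.ndarray, quality: int, method: str = "blockdct") -> np.ndarray:
    """Quality-tiered degradation of a grayscale image.

    ``blockdct`` (default) quantizes orthonormal 8x8 block-DCT coefficients
    with step ``2400 / quality`` — the JPEG artifact family without a codec.
    Distortion increases, in the mean over a batch, as quality decreases;
    infinite quality (``quality=inf`` or step 0) is the identity.
    ``jpeg`` round-trips through an actual JPEG encode at that quality.
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError("degrade expects a 2D grayscale image")
    if method == "jpeg":
        buf = io.BytesIO()
        pil = PILImage.fromarray(np.clip(arr, 0, 255).astype(np.uint8), mode="L")
        pil.save(buf, format="JPEG", quality=int(quality))
        buf.seek(0)
        return np.asarray(PILImage.open(buf), dtype=float)
    if method != "blockdct":
        raise ValueError(f"unknown degradation method {method!r}")
    if not np.isfinite(quality) or quality <= 0:
        if quality == np.inf:
            return arr.copy()
        raise ValueError("quality must be positive")
    step = _QUANT_BASE / float(quality)
    H, W = arr.shape
    Hc, Wc = (H // 8) * 8, (W // 8) * 8
    out = arr.copy()
    blocks = arr[:Hc, :Wc].reshape(Hc // 8, 8, Wc // 8, 8).transpose(0, 2, 1, 3)
    coef = sfft.dctn(blocks, axes=(2, 3), norm="ortho")
    coef = np.round(coef / step) * step
    rec = sfft.idctn(coef, axes=(2, 3), norm="ortho")
    out[:Hc, :Wc] = rec.transpose(0, 2, 1, 3).reshape(Hc, Wc)
    return np.clip(out, 0.0, 255.0)


def _exp_link(tau: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda d: 100.0 * np.exp(-np.sqrt(np.maximum(d, 0.0)) / tau)


@dataclass
class ObserverModel:
    """Simulated rater pool driven by a known ground-truth distance.

    ``distance_fn`` maps a (reference, degraded) pair to the ground-truth
    squared perceptual distance.  ``link`` maps distances to an expected
    rating on 0..100 and must be strictly monotone; the default
    (``link=None``) is ``rating = 100 exp(-d / tau)`` with ``tau`` set so the
    median training distance maps to rating 50, which makes DMOS rise with
    distortion.  ``link='affine'`` instead maps d^2 affinely onto ratings
    100..0 (DMOS proportional to d^2) — the noiseless identifiable link used
    by the parameter-recovery experiments.  Per-rater ratings are the
    expected rating plus Gaussian noise, clipped to [0, 100]; with
    ``round_ratings`` they are integers like real responses.
    """

    distance_fn: Callable[[np.ndarray, np.ndarray], float]
    link: str | Callable[[np.ndarray], np.ndarray] | None = None
    rater_noise_sd: float = 0.0
    n_raters: int = 5
    seed: int | None = None
    round_ratings: bool = True

    def __post_init__(self) -> None:
        if self.rater_noise_sd < 0:
            raise ValueError("rater_noise_sd must be >= 0")
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")

    def expected_ratings(self, d2: np.ndarray) -> np.ndarray:
        d2 = np.asarray(d2, dtype=float)
        if callable(self.link):
            exp = np.asarray(self.link(d2), dtype=float)
        elif self.link == "affine":
            top = d2.max()
            exp = 100.0 * (1.0 - d2 / top) if top > 0 else np.full_like(d2, 100.0)
        elif self.link is None:
            med = np.median(np.sqrt(d2))
            tau = med / np.log(2.0) if med > 0 else 1.0
            exp = _exp_link(tau)(d2)
        else:
            raise ValueError(f"unknown link {self.link!r}")
        return np.clip(exp, 0.0, 100.0)


def simulate_ratings(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    model: ObserverModel,
    image_ids: Sequence[str] | None = None,
    reference_ids: Sequence[str] | None = None,
    categories: Sequence[str] | None = None,
    quality_levels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """RatingsTable for (reference, degraded) pairs under an observer model.

    One row per rater per pair, in the shared CSV schema; the ``dmos``
    column is filled via ``dmos_from_rating``.  Deterministic under the
    model's seed.
    """
    n = len(pairs)
    d2 = np.array([model.distance_fn(a, b) for a, b in pairs], dtype=float)
    expected = model.expected_ratings(d2)
    rng = np.random.default_rng(model.seed)
    image_ids = image_ids or [f"img{i:05d}" for i in range(n)]
    reference_ids = reference_ids or [f"ref{i:05d}" for i in range(n)]
    categories = categories or ["synthetic"] * n
    quality_levels = quality_levels if quality_levels is not None else [0] * n
    rows = []
    for i in range(n):
        noise = rng.normal(0.0, model.rater_noise_sd, size=model.n_raters) \
            if model.rater_noise_sd > 0 else np.zeros(model.n_raters)
        ratings = np.clip(expected[i] + noise, 0.0, 100.0)
        if model.round_ratings:
            ratings = np.round(ratings)
        for k, r in enumerate(ratings):
            rows.append(
                (image_ids[i], reference_ids[i], categories[i],
                 quality_levels[i], f"s{k:03d}", float(r), dmos_from_rating(r))
            )
    return pd.DataFrame(rows, columns=RATINGS_COLUMNS)


def build_manifest(
    spec: SceneSpec = SceneSpec(),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dataset manifest and empty ratings skeleton for a SceneSpec.

    The manifest lists every original and degraded image with category and
    tier.  The skeleton has one row per rating slot: each degraded image is
    assigned ``raters_per_image`` subjects by partitioning the originals,
    once per rater group, into per-subject sets of ``images_per_subject``
    references (all four degraded tiers of a reference go to the same
    subject within a group, as in the source paradigm).
    """
    rng = np.random.default_rng(seed)
    cats = [f"cat{c:02d}" for c in range(spec.n_categories)]
    refs = [
        (f"{cat}_r{j:04d}", cat)
        for cat in cats
        for j in range(spec.refs_per_category)
    ]
    originals = pd.DataFrame(refs, columns=["reference_id", "category"])
    degraded = pd.DataFrame(
        [
            (f"{rid}_q{q:02d}", rid, cat, q)
            for rid, cat in refs
            for q in spec.quality_tiers
        ],
        columns=["image_id", "reference_id", "category", "quality_level"],
    )
    manifest = pd.concat(
        [
            originals.assign(image_id=originals.reference_id, quality_level=np.nan,
                             kind="original"),
            degraded.assign(kind="degraded"),
        ],
        ignore_index=True,
    )[["image_id", "reference_id", "category", "quality_level", "kind"]]

    # subject assignment: one permutation of the originals per rater group,
    # chunked into per-subject sets
    slot_rows = []
    ref_ids = originals.reference_id.to_numpy()
    by_ref = {rid: grp.image_id.tolist() for rid, grp in degraded.groupby("reference_id")}
    for g in range(spec.raters_per_image):
        order = rng.permutation(ref_ids)
        for s in range(spec.group_size):
            subject = f"g{g}s{s:03d}"
            chunk = order[s * spec.images_per_subject : (s + 1) * spec.images_per_subject]
            for rid in chunk:
                for img_id in by_ref[rid]:
                    slot_rows.append((img_id, rid, subject))
    slots = pd.DataFrame(slot_rows, columns=["image_id", "reference_id", "subject_id"])
    skeleton = slots.merge(
        degraded[["image_id", "category", "quality_level"]], on="image_id"
    ).assign(rating=np.nan, dmos=np.nan)[RATINGS_COLUMNS]
    return manifest, skeleton
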
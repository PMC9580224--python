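"""Connectivity kernels, dense perceptual Jacobians, and the DOG-derived CSF.

The perceptual operator P is a D x D matrix whose off-diagonal entries encode
pixel-pixel interactions in the early visual stream.  Two closed-form
connectivity profiles are provided: an isotropic Gaussian of retinotopic
distance (retinal ganglion / cortical pooling) and a center-surround
difference of Gaussians (DOG), the classic bipolar/ganglion receptive-field
shape.  Both are functions of the 2D Euclidean distance, in pixels, between
two locations on the image grid.

The power spectrum of the normalized DOG profile is a hypothesized contrast
sensitivity function (CSF); :func:`csf_from_dog` computes it on a discrete
frequency axis in cycles per degree of visual angle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_DEGREES_PER_PIXEL",
    "GaussianParams",
    "DOGParams",
    "GridGeometry",
    "Jacobian",
    "CsfCurve",
    "gauss",
    "dog",
    "build_jacobian",
    "build_stencil",
    "csf_from_dog",
]

logger = logging.getLogger(__name__)

#: Angular size of the center pixel under the laboratory viewing geometry
#: (50.8 cm from the display); configurable everywhere it is used because
#: published pixel<->degree conversions for this setup are not consistent.
DEFAULT_DEGREES_PER_PIXEL = 0.0619

#: Dense Jacobians above this dimensionality are refused; use the
#: convolutional path (``build_stencil`` + ``metric.convolutional_distance``).
DEFAULT_DENSE_CAP = 4096


@dataclass(frozen=True)
class GaussianParams:
    """Isotropic Gaussian connectivity, ``exp(-d^2 / 2 sigma^2)``.

    Parameters
    ----------
    sigma : float
        Width of the profile in pixels; must be positive.
    degrees_per_pixel : float
        Angular scale used when converting to degrees of visual angle.
    """

    sigma: float
    degrees_per_pixel: float = DEFAULT_DEGREES_PER_PIXEL

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.degrees_per_pixel > 0:
            raise ValueError("degrees_per_pixel must be > 0")

    @property
    def max_sigma(self) -> float:
        return self.sigma

    def weight(self, d):
        return gauss(d, self)


@dataclass(frozen=True)
class DOGParams:
    """Center-surround difference-of-Gaussians connectivity.

    ``(1/(1+alpha)) exp(-d^2/2 sc^2) - (alpha/(1+alpha)) exp(-d^2/2 ss^2)``
    with a narrow center ``sc`` and a broader surround ``ss`` (pixels);
    ``alpha`` is the dimensionless surround/center height ratio.
    """

    sigma_center: float
    sigma_surround: float
    alpha: float
    degrees_per_pixel: float = DEFAULT_DEGREES_PER_PIXEL

    def __post_init__(self) -> None:
        if not self.sigma_center > 0:
            raise ValueError("sigma_center must be > 0")
        if not self.sigma_surround > self.sigma_center:
            raise ValueError(
                "sigma_surround must exceed sigma_center "
                f"({self.sigma_surround} <= {self.sigma_center})"
            )
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not self.degrees_per_pixel > 0:
            raise ValueError("degrees_per_pixel must be > 0")

    @property
    def max_sigma(self) -> float:
        return self.sigma_surround

    def weight(self, d):
        return dog(d, self)


KernelParams = GaussianParams | DOGParams


def gauss(d, params: GaussianParams):
    """Gaussian connectivity weight at retinotopic distance ``d`` (pixels).

    Vectorized over ``d``; returns values in (0, 1] with ``gauss(0) == 1``.
    """
    d = np.asarray(d, dtype=float)
    out = np.exp(-(d**2) / (2.0 * params.sigma**2))
    return out if out.ndim else float(out)


def dog(d, params: DOGParams):
    """DOG connectivity weight at retinotopic distance ``d`` (pixels).

    At ``alpha = 0`` this reduces to ``gauss(d, sigma_center)``.  Note
    ``dog(0) = (1 - alpha) / (1 + alpha)``, which is not 1 in general.
    """
    d = np.asarray(d, dtype=float)
    a = params.alpha
    center = np.exp(-(d**2) / (2.0 * params.sigma_center**2))
    surround = np.exp(-(d**2) / (2.0 * params.sigma_surround**2))
    out = (center - a * surround) / (1.0 + a)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GridGeometry:
    """Row-major linearization of an ``height x width`` pixel grid."""

    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("grid must be nonempty")

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def coordinates(self) -> np.ndarray:
        """(D, 2) array of (row, col) coordinates in linearization order."""
        rows, cols = np.indices((self.height, self.width))
        return np.column_stack([rows.ravel(), cols.ravel()]).astype(float)

    def pairwise_distances(self) -> np.ndarray:
        """D x D matrix of 2D Euclidean inter-pixel distances, in pixels."""
        xy = self.coordinates()
        diff = xy[:, None, :] - xy[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


@dataclass
class Jacobian:
    """Symmetric, unit-diagonal perceptual operator on a pixel grid.

    ``entries`` is the dense D x D matrix P; ``geometry`` records the grid
    (or tile) whose row-major linearization indexes it.
    """

    entries: np.ndarray
    geometry: GridGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        P = np.asarray(self.entries, dtype=float)
        D = self.geometry.n_pixels
        if P.shape != (D, D):
            raise ValueError(f"entries shape {P.shape} != ({D}, {D})")
        if not np.all(np.isfinite(P)):
            raise ValueError("Jacobian entries must be finite")
        if not np.array_equal(P, P.T):
            raise ValueError("Jacobian must be symmetric")
        if not np.all(np.diag(P) == 1.0):
            raise ValueError("Jacobian diagonal must be exactly 1")
        self.entries = P

    @property
    def dim(self) -> int:
        return self.geometry.n_pixels


def _apply_diagonal_mode(values: np.ndarray, center: float, mode: str) -> np.ndarray:
    if mode == "force_one":
        return values
    if mode == "normalize_by_center":
        if center == 0.0:
            raise ValueError(
                "kernel(0) = 0; cannot normalize by center (alpha = 1 DOG)"
            )
        return values / center
    raise ValueError(f"unknown diagonal_mode: {mode!r}")


def build_jacobian(
    geometry: GridGeometry,
    kernel: KernelParams,
    diagonal_mode: str = "force_one",
    truncation_radius: float | None = None,
    dense_cap: int = DEFAULT_DENSE_CAP,
) -> Jacobian:
    """Dense approach-I Jacobian: P[i, j] = kernel(d_ret(i, j)).

    ``diagonal_mode`` resolves the tension between raw kernel values and the
    unit-diagonal requirement: ``force_one`` (default) keeps raw off-diagonal
    weights and overwrites the diagonal with 1; ``normalize_by_center``
    divides every entry by kernel(0).  Either way the diagonal ends exactly 1.

    ``truncation_radius`` zeroes entries with d_ret > radius, matching a
    stencil built with the same radius (the convolutional-path contract).
    """
    D = geometry.n_pixels
    if D > dense_cap:
        raise ValueError(
            f"grid has {D} pixels > dense cap {dense_cap}; "
            "use build_stencil + convolutional_distance instead"
        )
    dist = geometry.pairwise_distances()
    P = np.asarray(kernel.weight(dist), dtype=float)
    P = _apply_diagonal_mode(P, float(kernel.weight(0.0)), diagonal_mode)
    if truncation_radius is not None:
        P[dist > truncation_radius] = 0.0
    np.fill_diagonal(P, 1.0)
    # symmetrize bitwise: kernel of a symmetric distance matrix is already
    # symmetric analytically, but enforce exact equality
    P = np.triu(P) + np.triu(P, 1).T
    return Jacobian(P, geometry, meta={"kernel": kernel, "diagonal_mode": diagonal_mode})


def default_truncation_radius(kernel: KernelParams) -> int:
    """ceil(4 sigma_max): truncated tail < 3e-4 of the kernel peak."""
    return max(1, math.ceil(4.0 * kernel.max_sigma))


def build_stencil(
    kernel: KernelParams,
    truncation_radius: float | None = None,
    diagonal_mode: str = "force_one",
) -> np.ndarray:
    """Square odd-sized 2D stencil of kernel weights over integer offsets.

    The center value follows ``diagonal_mode`` (1 under both policies);
    weights at offsets with Euclidean magnitude beyond the radius are zeroed
    so that the stencil matches a dense Jacobian built with the same
    ``truncation_radius``.
    """
    if truncation_radius is None:
        truncation_radius = default_truncation_radius(kernel)
    if truncation_radius < 1:
        raise ValueError("truncation_radius must be >= 1")
    if truncation_radius < kernel.max_sigma:
        logger.warning(
            "stencil radius %.3g < kernel sigma %.3g: substantial tail truncated",
            truncation_radius,
            kernel.max_sigma,
        )
    r = math.ceil(truncation_radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d = np.sqrt(dy**2 + dx**2)
    S = np.asarray(kernel.weight(d), dtype=float)
    S = _apply_diagonal_mode(S, float(kernel.weight(0.0)), diagonal_mode)
    S[d > truncation_radius] = 0.0
    S[r, r] = 1.0
    return S


@dataclass(frozen=True)
class CsfCurve:
    """Discrete contrast sensitivity curve from a DOG profile.

    ``frequencies`` are in cycles per degree (DC excluded), ``power`` is the
    scaled DFT power per retained bin, ``power_db = 10 log10(1 + power)``.
    """

    frequencies: np.ndarray
    power: np.ndarray
    power_db: np.ndarray

    @property
    def peak_frequency(self) -> float:
        """Frequency (cycles/degree) of the maximum-power bin."""
        return float(self.frequencies[np.argmax(self.power)])


def csf_from_dog(
    params: DOGParams,
    n_half: int = 128,
    degrees_per_pixel: float | None = None,
) -> CsfCurve:
    """CSF as the power spectrum of the normalized DOG profile.

    Samples DOG at integer pixel offsets ``-n_half..n_half``, divides by
    DOG(0), takes the DFT of the N = 2 n_half + 1 samples, retains the
    positive-frequency bins 2..n_half+1 (1-based; DC excluded), and forms
    power ``(2/N) |z|^2``.  Retained bin m (1-based) maps to frequency
    ``(m - 1) / (N * degrees_per_pixel)`` cycles per degree.

    ``degrees_per_pixel`` overrides the value carried by ``params``; exposing
    it matters because the published pixel<->degree conversions for the
    reference viewing geometry are mutually inconsistent, and the CSF peak in
    cycles/degree scales inversely with it.
    """
    scale = params.degrees_per_pixel if degrees_per_pixel is None else degrees_per_pixel
    if not scale > 0:
        raise ValueError("degrees_per_pixel must be > 0")
    center = dog(0.0, params)
    if center == 0.0:
        raise ValueError("DOG(0) = 0 (alpha = 1): normalization degenerate")
    n = 2 * n_half + 1
    i = np.arange(-n_half, n_half + 1)
    y = dog(i, params) / center
    z = np.fft.fft(y)
    power = (2.0 / n) * np.abs(z[1 : n_half + 1]) ** 2
    freqs = np.arange(1, n_half + 1) / (n * scale)
    return CsfCurve(freqs, power, 10.0 * np.log10(1.0 + power))
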
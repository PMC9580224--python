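"""Distance engine: Euclidean, perceptual quadratic form, convolutional and
tiled variants, and the strain tensor.

All distances are reported squared (d^2), in squared luminance units, on 2D
float arrays.  The perceptual distance is the quadratic form

    d_P^2(s, s') = (s' - s)^T P^T P (s' - s)

where P is a symmetric unit-diagonal Jacobian.  Because P^T P is positive
semidefinite, every variant is nonnegative even when P has negative
off-diagonal couplings.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .kernels import GridGeometry, Jacobian

__all__ = [
    "preprocess",
    "euclidean_distance",
    "perceptual_distance",
    "convolutional_distance",
    "tiled_distance",
    "tile_differences",
    "strain_tensor",
    "first_order_distance",
]

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights used for color -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def preprocess(img: np.ndarray, stretch: bool = True) -> np.ndarray:
    """Grayscale + luminance-stretch an image to the [0, 255] range.

    Color inputs (H, W, 3) are converted with BT.601 luma weights; the
    result is linearly stretched so min -> 0 and max -> 255.  A constant
    image cannot be stretched and raises ``ValueError``.
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        arr = arr @ _LUMA
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a nonempty 2D image, got shape {np.shape(img)}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if stretch:
        lo, hi = arr.min(), arr.max()
        if hi == lo:
            raise ValueError("constant image: luminance stretch is degenerate")
        arr = (arr - lo) / (hi - lo) * 255.0  # endpoints land exactly on 0, 255
    return arr


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("images must be 2D")
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def euclidean_distance(a: np.ndarray, b: np.ndarray, mean: bool = False) -> float:
    """Squared Euclidean distance; ``mean=True`` divides by D (pixel MSE)."""
    a, b = _check_pair(a, b)
    d2 = float(np.sum((b - a) ** 2))
    return d2 / a.size if mean else d2


def _jacobian_matrix(P: Jacobian | np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if isinstance(P, Jacobian):
        if (P.geometry.height, P.geometry.width) != shape:
            raise ValueError(
                f"Jacobian geometry {P.geometry.height}x{P.geometry.width} "
                f"does not match image shape {shape[0]}x{shape[1]}"
            )
        return P.entries
    P = np.asarray(P, dtype=float)
    D = shape[0] * shape[1]
    if P.shape != (D, D):
        raise ValueError(f"operator shape {P.shape} incompatible with image ({D} pixels)")
    return P


def perceptual_distance(a: np.ndarray, b: np.ndarray, P: Jacobian | np.ndarray) -> float:
    """Full quadratic form Delta^T P^T P Delta on the linearized difference."""
    a, b = _check_pair(a, b)
    M = _jacobian_matrix(P, a.shape)
    delta = (b - a).ravel()
    v = M @ delta
    return float(v @ v)


def convolutional_distance(a: np.ndarray, b: np.ndarray, stencil: np.ndarray) -> float:
    """Translation-invariant realization of the perceptual quadratic form.

    Correlates the difference image with the 2D stencil under zero padding
    and sums the squared response.  For a stencil built from a kernel with a
    given truncation radius, this equals ``perceptual_distance`` with the
    dense Jacobian built from the same kernel and radius on the same grid —
    without ever materializing the D x D matrix.
    """
    a, b = _check_pair(a, b)
    stencil = np.asarray(stencil, dtype=float)
    if stencil.ndim != 2 or stencil.shape[0] % 2 == 0 or stencil.shape[1] % 2 == 0:
        raise ValueError("stencil must be a 2D odd-sized array")
    filtered = ndimage.correlate(b - a, stencil, mode="constant", cval=0.0)
    return float(np.sum(filtered**2))


def tile_differences(
    a: np.ndarray,
    b: np.ndarray,
    tile: tuple[int, int] = (8, 8),
    edge: str = "refuse",
) -> np.ndarray:
    """Per-tile linearized differences, shape (n_tiles, th*tw), row-major.

    ``edge='refuse'`` (default) raises on images not divisible by the tile;
    ``edge='crop'`` crops to the largest tile multiple (logged).
    """
    a, b = _check_pair(a, b)
    th, tw = tile
    H, W = a.shape
    if H % th or W % tw:
        if edge == "crop":
            H, W = (H // th) * th, (W // tw) * tw
            if H == 0 or W == 0:
                raise ValueError("image smaller than one tile")
            logger.info("cropping %s to %dx%d for %dx%d tiling", a.shape, H, W, th, tw)
            a, b = a[:H, :W], b[:H, :W]
        else:
            raise ValueError(
                f"image {a.shape} not divisible by tile {tile}; pass edge='crop'"
            )
    delta = b - a
    tiles = delta.reshape(H // th, th, W // tw, tw).transpose(0, 2, 1, 3)
    return tiles.reshape(-1, th * tw)


def tiled_distance(
    a: np.ndarray,
    b: np.ndarray,
    P_tile: Jacobian | np.ndarray,
    tile: tuple[int, int] = (8, 8),
    edge: str = "refuse",
) -> float:
    """Sum of per-tile perceptual quadratic forms (approach-II scoring)."""
    deltas = tile_differences(a, b, tile=tile, edge=edge)
    M = P_tile.entries if isinstance(P_tile, Jacobian) else np.asarray(P_tile, float)
    if M.shape != (deltas.shape[1], deltas.shape[1]):
        raise ValueError(
            f"tile operator is {M.shape}, expected {(deltas.shape[1],) * 2} "
            f"for {tile} tiles"
        )
    v = deltas @ M.T
    return float(np.sum(v * v))


def strain_tensor(P: Jacobian | np.ndarray) -> np.ndarray:
    """Symmetrized first-order strain, eps = ((P - I) + (P - I)^T) / 2.

    For a unit-diagonal P the diagonal of eps is zero: uniform dilation is
    not measurable from relative distance judgments.
    """
    M = P.entries if isinstance(P, Jacobian) else np.asarray(P, dtype=float)
    G = M - np.eye(M.shape[0])
    return (G + G.T) / 2.0


def first_order_distance(a: np.ndarray, b: np.ndarray, eps: np.ndarray) -> float:
    """Delta^T (I + 2 eps) Delta: perceptual distance with the second-order
    term (grad u)(grad u)^T dropped.  Equals the Euclidean distance plus
    2 Delta^T eps Delta, and may be negative for large strains."""
    a, b = _check_pair(a, b)
    delta = (b - a).ravel()
    eps = np.asarray(eps, dtype=float)
    return float(delta @ delta + 2.0 * delta @ (eps @ delta))
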
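"""File formats: raster images (PNG/BMP/PGM), ratings CSV, Jacobian TSV,
and YAML run configuration.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image as PILImage

from .kernels import GridGeometry, Jacobian
from .synthetic import RATINGS_COLUMNS

__all__ = [
    "read_image",
    "write_image",
    "read_ratings",
    "write_ratings",
    "read_jacobian",
    "write_jacobian",
    "load_config",
]

logger = logging.getLogger(__name__)


def read_image(path) -> np.ndarray:
    """Load a raster image as a float array (2D grayscale or H x W x 3)."""
    try:
        with PILImage.open(path) as im:
            im.load()
            if im.mode not in ("L", "I;16", "I", "F", "RGB", "RGBA"):
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=float)
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr


def write_image(path, img: np.ndarray) -> None:
    """Write a grayscale image; 8-bit round-trips losslessly for PNG/BMP/PGM."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError("write_image expects a 2D grayscale array")
    if np.issubdtype(arr.dtype, np.floating):
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("float image out of [0, 255]; preprocess first")
        arr = np.round(arr).astype(np.uint8)
    PILImage.fromarray(arr.astype(np.uint8), mode="L").save(path)


def read_ratings(path, check_dmos: bool = True) -> pd.DataFrame:
    """Load a ratings CSV in the shared schema, validating as it goes.

    Raises on missing columns; recomputes DMOS from the rating column and
    reports rows where the stored value disagrees.  Missing ``dmos`` values
    are filled from ``rating``.
    """
    df = pd.read_csv(path)
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ratings file {path} missing column(s): {missing}")
    rated = df["rating"].notna()
    if rated.any():
        r = df.loc[rated, "rating"].astype(float)
        if ((r < 0) | (r > 100)).any():
            bad = df.index[rated][(r < 0) | (r > 100)].tolist()[:10]
            raise ValueError(f"ratings out of [0, 100] at rows {bad}")
        expected = 1.0 - r / 100.0
        have = df.loc[rated, "dmos"]
        if check_dmos and have.notna().any():
            mism = rated.copy()
            mism.loc[rated] = have.notna() & ~np.isclose(have, expected, atol=1e-9)
            if mism.any():
                raise ValueError(
                    f"dmos disagrees with 1 - rating/100 at rows "
                    f"{df.index[mism].tolist()[:10]}"
                )
        df.loc[rated, "dmos"] = expected
    return df[RATINGS_COLUMNS]


def write_ratings(path, table: pd.DataFrame) -> None:
    missing = [c for c in RATINGS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ratings table missing column(s): {missing}")
    table[RATINGS_COLUMNS].to_csv(path, index=False)


def write_jacobian(path, jac: Jacobian, header: dict | None = None) -> None:
    """Dense tab-separated matrix with '#' comment lines recording config."""
    lines = [f"# perceptstrain jacobian {jac.geometry.height}x{jac.geometry.width} tile"]
    for key, val in (header or {}).items():
        lines.append(f"# {key}: {val}")
    body = "\n".join(
        "\t".join(repr(float(v)) for v in row) for row in jac.entries
    )
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_jacobian(path, geometry: GridGeometry | None = None,
                  bounds: tuple[float, float] | None = None) -> Jacobian:
    """Load and validate a TSV Jacobian (symmetry, unit diagonal, bounds)."""
    text = Path(path).read_text().splitlines()
    rows = [ln for ln in text if ln.strip() and not ln.startswith("#")]
    M = np.array([[float(v) for v in ln.split("\t")] for ln in rows])
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {M.shape}")
    D = M.shape[0]
    if geometry is None:
        side = math.isqrt(D)
        if side * side != D:
            raise ValueError(f"{path}: {D} pixels is not a square tile; pass geometry")
        geometry = GridGeometry(side, side)
    bad = np.argwhere(M != M.T)
    if bad.size:
        raise ValueError(f"{path}: asymmetric at cells {bad[:10].tolist()}")
    off = np.flatnonzero(np.diag(M) != 1.0)
    if off.size:
        raise ValueError(f"{path}: diagonal != 1 at indices {off[:10].tolist()}")
    if bounds is not None:
        lo, hi = bounds
        bad = np.argwhere((M < lo) | (M > hi))
        if bad.size:
            raise ValueError(f"{path}: entries outside {bounds} at {bad[:10].tolist()}")
    return Jacobian(M, geometry)


def load_config(path) -> dict:
    """YAML run configuration as a plain dict (empty file -> empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
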
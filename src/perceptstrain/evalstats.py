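"""Evaluation statistics: DMOS conversion, Pearson correlation on linear and
log-log axes, permutation tests, Fisher r-to-z model comparison, Bonferroni.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats as sps

__all__ = [
    "dmos_from_rating",
    "pearson",
    "permutation_pvalue",
    "bonferroni",
    "fisher_compare",
    "fisher_compare_folds",
]

logger = logging.getLogger(__name__)


def dmos_from_rating(rating):
    """DMOS = 1 - rating/100 for ratings on the 0..100 difference scale.

    DMOS 0 means no perceptible difference; 1 means rated 100% different.
    (Note the rating scale asks *how different* the degraded image looks, so
    the printed conversion inverts it; it is implemented exactly as defined.)
    """
    r = np.asarray(rating, dtype=float)
    if np.any((r < 0) | (r > 100)):
        raise ValueError("ratings must lie in [0, 100]")
    out = 1.0 - r / 100.0
    return out if out.ndim else float(out)


def _loglog_filter(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = (x > 0) & (y > 0)
    dropped = int(np.size(x) - keep.sum())
    if dropped:
        logger.info("log-log Pearson: dropping %d nonpositive pair(s)", dropped)
    return np.log10(x[keep]), np.log10(y[keep])


def pearson(scores, dmos, axes: str = "linear") -> float:
    """Pearson r between model scores and DMOS, on raw or log10 axes.

    Under ``axes='loglog'`` pairs with a nonpositive value on either side
    are excluded (a DMOS of exactly 0 has no logarithm); the count of
    dropped pairs is logged.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(dmos, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and dmos must be equal-length 1D arrays")
    if axes == "loglog":
        x, y = _loglog_filter(x, y)
    elif axes != "linear":
        raise ValueError(f"axes must be 'linear' or 'loglog', got {axes!r}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def permutation_pvalue(
    scores,
    dmos,
    n_perm: int = 9999,
    seed: int | None = None,
    axes: str = "linear",
) -> float:
    """Permutation p-value for |r| > 0: p = (1 + #{|r_perm| >= |r|}) / (1 + n_perm)."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(dmos, dtype=float)
    r_obs = abs(pearson(x, y, axes=axes))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r = abs(pearson(x, rng.permutation(y), axes=axes))
        if r >= r_obs - 1e-12:  # tolerate float ties
            count += 1
    return (1 + count) / (1 + n_perm)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-tailed p for the difference of two independent correlations.

    Fisher z-transforms each r and compares (z1 - z2) against a normal with
    variance 1/(n1-3) + 1/(n2-3).  The two samples are treated as
    independent, exactly as in the fold-wise model comparisons this
    implements (not a dependent-correlation test).
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the z transform")
        if n <= 3:
            raise ValueError("need n > 3 per sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * sps.norm.sf(abs(z)))


def fisher_compare_folds(fold_stats) -> float:
    """Mean of per-fold ``fisher_compare`` p-values.

    ``fold_stats`` is an iterable of (r1, n1, r2, n2) tuples, one per
    cross-validation fold; the comparison is run per fold and the p-values
    are averaged.
    """
    ps = [fisher_compare(*f) for f in fold_stats]
    if not ps:
        raise ValueError("no folds supplied")
    return float(np.mean(ps))
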
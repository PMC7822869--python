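"""Small shared statistical helpers.

These wrap scipy routines with the degenerate-input conventions used
throughout the pipeline: a two-group comparison with zero variance in both
groups and equal means is reported as p = 1 (no evidence of a difference)
rather than NaN, and percentages are rounded half-up to two decimals.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats


def percent(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to 2 decimals.

    Uses exact decimal arithmetic so 100*212/14005 -> 1.51 and
    100*234/13236 -> 1.77 regardless of binary floating point.
    """
    if total <= 0:
        return 0.0
    q = (Decimal(100) * Decimal(int(count)) / Decimal(int(total))).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def equal_var_ttest(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t test, degenerate cases resolved.

    Returns (t, p). Zero variance in both groups: p = 1 when the means are
    equal, p = 0 when they differ (the groups are perfectly separated).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def vectorized_ttest(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance t test with NaN-aware groups.

    ``a`` and ``b`` are (genes x samples) arrays; NaN entries are excluded
    observation-wise. Rows where either group has <2 valid observations get
    p = NaN. Zero-variance rows follow the :func:`equal_var_ttest` convention.
    """
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=True, nan_policy="omit")
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        var_a = np.nanvar(a, axis=1)
        var_b = np.nanvar(b, axis=1)
    degenerate = (var_a == 0.0) & (var_b == 0.0)
    same = degenerate & (mean_a == mean_b)
    diff = degenerate & (mean_a != mean_b)
    t[same], p[same] = 0.0, 1.0
    t[diff] = np.where(mean_a[diff] > mean_b[diff], np.inf, -np.inf)
    p[diff] = 0.0
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    too_few = (n_a < 2) | (n_b < 2)
    t[too_few] = np.nan
    p[too_few] = np.nan
    return t, p
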
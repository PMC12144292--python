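"""Expression–phenotype association.

Pearson correlation (with its exact t-based p-value), simple least-squares
regression whose slope test is the same t test, diameter-threshold group
comparisons, and the murine aneurysm call (>= 1.5-fold relative diameter).

Expression is analyzed on an abundance-increasing scale (-dCt or normalized
log expression); output headers state the scale.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import t_test

__all__ = ["pearson", "linreg", "threshold_groups", "aneurysmal", "percent"]


def percent(count: int, total: int) -> int:
    """Nearest-integer percentage, as printed in cohort characteristic tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return int(np.floor(100.0 * count / total + 0.5))  # half rounds up, as tables print


def _check_xy(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p from t = r*sqrt((n-2)/(1-r^2))."""
    x, y = _check_xy(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def linreg(x, y) -> tuple[float, float, float]:
    """Least-squares slope, intercept, and the slope's t-test p-value.

    The slope p-value is mathematically identical to the Pearson p on the
    same data.
    """
    x, y = _check_xy(x, y)
    if np.std(x) == 0:
        raise ValueError("regression undefined for constant x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


def threshold_groups(
    expr: pd.Series,
    diameters: pd.Series,
    cut_mm: float,
    tails: int = 2,
    welch: bool = False,
) -> dict:
    """Split samples at a diameter cut (<= cut vs > cut) and t-test expression.

    Returns the partition sizes, group means and the test result.  Samples
    must all carry a diameter; an empty stratum raises an error naming it.
    """
    expr, diameters = expr.align(diameters, join="inner")
    if expr.isna().any() or diameters.isna().any():
        raise ValueError("every sample needs both expression and diameter")
    small = expr[diameters <= cut_mm]
    large = expr[diameters > cut_mm]
    for name, grp in ((f"<= {cut_mm} mm", small), (f"> {cut_mm} mm", large)):
        if len(grp) == 0:
            raise ValueError(f"empty stratum: {name}")
    t, p = t_test(large, small, tails=tails, welch=welch, alternative="greater")
    return {
        "cut_mm": cut_mm,
        "n_small": int(len(small)),
        "n_large": int(len(large)),
        "mean_small": float(small.mean()),
        "mean_large": float(large.mean()),
        "t": t,
        "p": p,
    }


def aneurysmal(relative_diameter, threshold: float = 1.5):
    """Aneurysm call on relative (fold) diameter: True iff >= threshold."""
    rel = np.asarray(relative_diameter, dtype=float)
    if (rel <= 0).any():
        raise ValueError("relative diameters must be positive")
    out = rel >= threshold
    return bool(out) if out.ndim == 0 else out
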
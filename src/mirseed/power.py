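"""Power and sample size for the two-sample t design with family-wise control.

The experiment-wise error rate (EWER) over ``m`` simultaneous tests is
handled by Bonferroni: each test runs at ``alpha_family / m``.  Power for a
true mean difference ``delta`` uses the noncentral t distribution with
noncentrality ``delta / sqrt(sd1^2/n1 + sd2^2/n2)`` and ``n1 + n2 - 2``
degrees of freedom.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerDesign", "per_test_alpha", "t_power", "n_for_power"]


@dataclass(frozen=True)
class PowerDesign:
    n1: int
    n2: int
    delta: float
    sd1: float
    sd2: float
    alpha_family: float = 0.05
    m: int = 1
    tails: int = 2

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("standard deviations must be positive")
        if not 0 < self.alpha_family < 1:
            raise ValueError("alpha_family must lie in (0, 1)")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")

    def power(self) -> float:
        alpha = per_test_alpha(self.alpha_family, self.m)
        return t_power(
            self.n1, self.n2, self.delta, self.sd1, self.sd2, alpha=alpha, tails=self.tails
        )


def per_test_alpha(alpha_family: float, m: int, method: str = "bonferroni") -> float:
    """Per-test significance level controlling the family-wise rate over m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha_family < 1:
        raise ValueError("alpha_family must lie in (0, 1)")
    if method != "bonferroni":
        raise ValueError(f"unknown method {method!r}")
    return alpha_family / m


def t_power(
    n1: int,
    n2: int,
    delta: float,
    sd1: float,
    sd2: float | None = None,
    alpha: float = 0.05,
    tails: int = 2,
) -> float:
    """Power of the two-sample t test at per-test level ``alpha``."""
    sd2 = sd1 if sd2 is None else sd2
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    ncp = delta / np.sqrt(sd1**2 / n1 + sd2**2 / n2)

    def _tail(stat: float, upper: bool) -> float:
        val = stats.nct.sf(stat, df, ncp) if upper else stats.nct.cdf(stat, df, ncp)
        if not np.isfinite(val):  # scipy far-tail instability: normal fallback
            val = stats.norm.sf(stat - ncp) if upper else stats.norm.cdf(stat - ncp)
        return float(np.clip(val, 0.0, 1.0))

    if tails == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        power = _tail(tcrit, upper=True) + _tail(-tcrit, upper=False)
    elif tails == 1:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        power = _tail(tcrit, upper=True) if ncp >= 0 else _tail(-tcrit, upper=False)
    else:
        raise ValueError("tails must be 1 or 2")
    return float(min(power, 1.0))


def n_for_power(
    target_power: float,
    delta: float,
    sd1: float,
    sd2: float | None = None,
    alpha: float = 0.05,
    tails: int = 2,
    ratio: float = 1.0,
    n_max: int = 10_000_000,
) -> tuple[int, int]:
    """Smallest (n1, n2 = ceil(ratio * n1)) with power >= target_power.

    ``ratio`` is n2/n1 (e.g. 0.75 for a 200:150 allocation).  Monotone
    doubling search followed by bisection.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    if delta == 0:
        raise ValueError("power beyond alpha is unreachable with delta = 0")
    if ratio <= 0:
        raise ValueError("ratio must be positive")

    def pw(n1: int) -> float:
        n2 = max(2, int(np.ceil(ratio * n1)))
        return t_power(n1, n2, delta, sd1, sd2, alpha=alpha, tails=tails)

    lo, hi = 2, 4
    while pw(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError("target power unreachable within n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if pw(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo, max(2, int(np.ceil(ratio * lo)))
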
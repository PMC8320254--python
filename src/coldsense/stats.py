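"""Proportion, distribution and regression statistics used by the pipeline.

Conventions: Wilson score intervals without continuity correction for
proportions, Pearson χ² without Yates correction for 2×2 tables, the
asymptotic two-sample Kolmogorov-Smirnov test for area distributions, and
ordinary least squares with a t-test on the slope difference for recruitment
lines. All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ProportionResult",
    "LineFit",
    "wilson_ci",
    "chi2_2x2",
    "ks_two_sample",
    "ols_line",
    "compare_slopes",
]


@dataclass(frozen=True)
class ProportionResult:
    """A binomial proportion with its Wilson score confidence interval."""

    k: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    level: float = 0.95


class LineFit(NamedTuple):
    slope: float
    intercept: float
    r2: float
    se_slope: float


def wilson_ci(k: int, n: int, level: float = 0.95) -> ProportionResult:
    """Wilson score interval for ``k`` successes in ``n`` trials.

    No continuity correction; the interval is the one recommended by Brown,
    Cai & DasGupta for binomial proportions. ``k = 0`` pins the lower bound
    at 0 and ``k = n`` pins the upper bound at 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    low, high = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return ProportionResult(
        k=int(k), n=int(n), p_hat=k / n, ci_low=float(low), ci_high=float(high),
        level=level,
    )


def chi2_2x2(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson χ² test (no continuity correction) on a 2×2 count table.

    Returns ``(statistic, df, p)`` with df = 1 and the p-value from the
    χ²(1) upper tail. Raises if any row or column margin is zero.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) <= 0).any() or (obs.sum(axis=1) <= 0).any():
        raise ValueError("every row and column margin must be positive")
    stat, p, df, _ = scipy.stats.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test, asymptotic p-value.

    D is the supremum distance between the two empirical CDFs; the p-value
    comes from the Kolmogorov distribution at the effective sample size
    n_a·n_b/(n_a+n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must contain at least 2 values")
    res = scipy.stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ols_line(x: Sequence[float], y: Sequence[float]) -> LineFit:
    """Ordinary least-squares line ``y = slope·x + intercept``.

    Returns the slope, intercept, r² and the standard error of the slope.
    Requires at least 3 points and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    res = scipy.stats.linregress(x, y)
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        se_slope=float(res.stderr),
    )


def compare_slopes(
    fit1: LineFit, fit2: LineFit, n1: int, n2: int
) -> tuple[float, int, float]:
    """Two-sided t-test for equality of two independent regression slopes.

    t = (b₁ − b₂)/√(se₁² + se₂²) on n₁ + n₂ − 4 degrees of freedom.
    """
    df = n1 + n2 - 4
    if df < 1:
        raise ValueError("need n1 + n2 >= 5 points in total")
    se = float(np.hypot(fit1.se_slope, fit2.se_slope))
    if se == 0:
        t = 0.0 if fit1.slope == fit2.slope else float("inf")
    else:
        t = (fit1.slope - fit2.slope) / se
    p = 2 * scipy.stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)
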
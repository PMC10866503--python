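"""Shared statistical primitives.

Small, pure functions used by every stage of the pipeline: Benjamini-Hochberg
FDR adjustment, Welch's unequal-variance t-test, Spearman rank correlation,
reduced major axis (RMA) regression, the 2x2 Pearson chi-square test of
independence, and the analytic moments of the hypergeometric overlap null
(the closed-form counterpart of the permutation tests in
:mod:`parevol.enrichment`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "bh_adjust",
    "welch_t",
    "spearman_r",
    "rma_fit",
    "chisq_independence",
    "hypergeom_overlap_moments",
]


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its degrees of freedom and two-sided p-value."""

    statistic: float
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are treated as untested: they are excluded from the number of
    tests ``m`` and propagated as NaN in the output.  Output order matches
    input order; adjusted values are capped at 1 and made monotone in the
    sorted-p ordering.

    Parameters
    ----------
    p_values : array-like of float
        Raw p-values in [0, 1]; NaN allowed.

    Returns
    -------
    ndarray
        Adjusted p-values, same shape as the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    m = int(finite.sum())
    if m == 0:
        return out
    pv = p[finite]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[finite] = restored
    return out


def welch_t(x, y) -> TestResult:
    """Welch two-sample t-test (unequal variances, two-sided).

    Uses the Welch-Satterthwaite approximation for the degrees of freedom.
    If both samples have zero variance and equal means the statistic is 0
    with p = 1 (the degenerate no-difference case).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, float(x.size + y.size - 2), 1.0)
        raise ValueError("both groups constant with different means: t undefined")
    sem2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(sem2)
    df = sem2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)))


def spearman_r(x, y, return_p: bool = False):
    """Spearman rank correlation (average ranks for ties).

    Returns NaN (with a warning) when either vector is constant, where rank
    correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman_r requires equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector: Spearman correlation undefined")
        return (np.nan, np.nan) if return_p else np.nan
    r, p = sps.spearmanr(x, y)
    return (float(r), float(p)) if return_p else float(r)


def rma_fit(x, y) -> tuple[float, float]:
    """Reduced major axis (standardized major axis) regression line.

    slope = sign(r) * sd(y)/sd(x); intercept = mean(y) - slope * mean(x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0:
        raise ValueError("rma_fit: x is constant")
    if sy == 0:
        raise ValueError("rma_fit: y is constant")
    r = np.corrcoef(x, y)[0, 1]
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def chisq_independence(table, continuity: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 count table.

    Continuity (Yates) correction is off by default; pass ``continuity=True``
    for small tables.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("chisq_independence expects a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal: chi-square undefined")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=continuity)
    return TestResult(float(stat), float(dof), float(p))


def hypergeom_overlap_moments(N: int, m1: int, m2: int) -> tuple[float, float]:
    """Mean and variance of the overlap of two random subsets of a universe.

    For subsets of sizes ``m1`` and ``m2`` drawn uniformly without replacement
    from ``N`` items, the intersection size is hypergeometric with
    mean m1*m2/N and variance m1*m2*(N-m1)*(N-m2) / (N^2*(N-1)).
    """
    if N <= 0:
        raise ValueError("background size must be positive")
    if not (0 <= m1 <= N and 0 <= m2 <= N):
        raise ValueError("set sizes must lie in [0, N]")
    mean = m1 * m2 / N
    if N == 1:
        return float(mean), 0.0
    var = m1 * m2 * (N - m1) * (N - m2) / (N**2 * (N - 1))
    return float(mean), float(var)
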
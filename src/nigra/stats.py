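"""Group-comparison and correlation statistics.

Thin, contract-pinning wrappers over scipy.stats: Mann-Whitney U with
midrank tie handling (exact enumeration for small tie-free samples), pooled
Student t-test (raw samples or summary statistics), Pearson chi-square
without continuity correction, Spearman rho, Kendall tau-b, and Bonferroni
alpha adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

#: largest min(n1, n2) for which the exact Mann-Whitney null is enumerated
EXACT_MW_MAX_N = 8


@dataclass
class CorrelationResult:
    method: Literal["spearman", "kendall_tau_b"]
    coefficient: float
    p_value: float
    n: int
    alpha_adjusted: float | None = None

    @property
    def significant_after_bonferroni(self) -> bool:
        if self.alpha_adjusted is None:
            raise ValueError("no adjusted alpha stored")
        return self.p_value < self.alpha_adjusted


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (midrank ties); exact for small tie-free samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # fully tied: U degenerate, no evidence
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def t_test(
    x: Sequence[float] | tuple[float, float, int],
    y: Sequence[float] | tuple[float, float, int],
) -> tuple[float, float]:
    """Pooled-variance two-sided Student t-test.

    Accepts raw samples, or (mean, sd, n) summary triples for published
    tables.
    """
    def is_summary(v) -> bool:
        return isinstance(v, tuple) and len(v) == 3

    if is_summary(x) or is_summary(y):
        if not (is_summary(x) and is_summary(y)):
            raise ValueError("mix of raw and summary inputs")
        (m1, s1, n1), (m2, s2, n2) = x, y
        if n1 < 2 or n2 < 2:
            raise ValueError("need n >= 2 per group")
        if s1 <= 0 or s2 <= 0:
            raise ValueError("degenerate (nonpositive) standard deviation")
        res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError("need n >= 2 per group")
        if np.std(x) == 0 and np.std(y) == 0 and np.mean(x) != np.mean(y):
            raise ValueError("degenerate zero-variance samples")
        res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], df=1, no continuity
    correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in 2x2 table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def spearman(x: Sequence[float], y: Sequence[float],
             alpha_adjusted: float | None = None) -> CorrelationResult:
    """Spearman rank correlation (Pearson on midranks), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult("spearman", float(rho), float(p), int(x.size), alpha_adjusted)


def kendall_tau_b(x: Sequence[float], y: Sequence[float],
                  alpha_adjusted: float | None = None) -> CorrelationResult:
    """Kendall tau-b with the standard tie corrections, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("all-tied input: tau-b undefined")
    tau, p = sps.kendalltau(x, y, variant="b")
    return CorrelationResult("kendall_tau_b", float(tau), float(p), int(x.size), alpha_adjusted)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance level alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
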
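"""Hypothesis tests and interval estimators for the cohort comparisons.

Continuous variables are compared with the two-sample equal-variance
t-test (raw samples or printed mean/SD/n summaries), ordinal variables
with the Mann-Whitney test, proportions with Fisher's exact test, and
multi-category comparisons with one-way ANOVA followed by Dunnett's test
against a reference category. Binomial confidence intervals use the
Wilson score method with continuity correction. All p-values are
two-tailed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "BinomialCI",
    "t_test_equal_var",
    "t_test_from_summary",
    "mann_whitney",
    "fisher_exact_2x2",
    "anova_dunnett",
    "wilson_ci_cc",
    "wilson_ci",
]


@dataclass
class TestResult:
    statistic: float
    p_two_tailed: float
    df: float | None = None
    exact: bool = False
    # Dunnett: per-non-reference-group adjusted p, keyed by group index
    adjusted_p: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0 or math.isnan(self.p_two_tailed)):
            raise ValueError(f"p-value out of [0,1]: {self.p_two_tailed}")


@dataclass
class BinomialCI:
    successes: int
    n: int
    level: float
    lo: float
    hi: float

    @property
    def estimate(self) -> float:
        return self.successes / self.n


def t_test_equal_var(x, y) -> TestResult:
    """Pooled-variance two-sample t-test, two-tailed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, 1.0, df=len(x) + len(y) - 2)
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(float(t), float(p), df=len(x) + len(y) - 2)


def t_test_from_summary(m1: float, s1: float, n1: int,
                        m2: float, s2: float, n2: int) -> TestResult:
    """Equal-variance t-test driven by printed mean/SD/n summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return TestResult(0.0, 1.0, df=n1 + n2 - 2)
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return TestResult(float(t), float(p), df=n1 + n2 - 2)


_EXACT_MAX_N = 8


def mann_whitney(x, y, method: str = "auto") -> TestResult:
    """Mann-Whitney U test, two-tailed.

    ``method``: "exact" (full enumeration; rejected in the presence of
    ties), "asymptotic" (tie-corrected normal approximation with
    continuity correction), or "auto" — exact when both groups have
    <= 8 observations and there are no ties, asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each sample needs >= 1 observation")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if method == "auto":
        method = ("exact" if len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N
                  and not has_ties else "asymptotic")
    if method == "exact" and has_ties:
        raise ValueError("exact method is undefined with ties; use asymptotic")
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(u), float(min(p, 1.0)), exact=(method == "exact"))


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test on a 2x2 count table, two-tailed.

    A table with a zero row or column margin is degenerate and returns
    p = 1 by convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(float(odds), float(p), exact=True)


def anova_dunnett(groups, reference_index: int = 0, *,
                  seed: int | None = 0) -> TestResult:
    """One-way ANOVA F test plus Dunnett's comparisons against a reference.

    Returns the overall F statistic and p, with ``adjusted_p`` holding
    the Dunnett-adjusted two-sided p-value for every non-reference group
    (keyed by its index in ``groups``). The multivariate-t adjustment is
    evaluated by randomized quasi-Monte Carlo integration; ``seed`` fixes
    it for reproducibility.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if not 0 <= reference_index < len(groups):
        raise ValueError(f"reference index {reference_index} out of range")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs >= 2 observations")

    f, p = sps.f_oneway(*groups)
    if math.isnan(f):  # all groups constant and equal
        f, p = 0.0, 1.0
    others = [g for i, g in enumerate(groups) if i != reference_index]
    other_idx = [i for i in range(len(groups)) if i != reference_index]
    res = sps.dunnett(*others, control=groups[reference_index],
                      alternative="two-sided", rng=seed)
    adjusted = {i: float(min(pv, 1.0))
                for i, pv in zip(other_idx, np.atleast_1d(res.pvalue))}
    return TestResult(float(f), float(min(p, 1.0)),
                      df=sum(len(g) for g in groups) - len(groups),
                      adjusted_p=adjusted)


def wilson_ci(successes: int, n: int, level: float = 0.95) -> BinomialCI:
    """Wilson score interval without continuity correction."""
    _check_counts(successes, n)
    z = sps.norm.ppf(1 - (1 - level) / 2)
    p = successes / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return BinomialCI(successes, n, level,
                      max(center - half, 0.0), min(center + half, 1.0))


def wilson_ci_cc(successes: int, n: int, level: float = 0.95) -> BinomialCI:
    """Wilson score interval with continuity correction, clamped to [0, 1].

    The corrected interval is wider than the plain Wilson interval and
    is the convention used for the sensitivity/specificity intervals in
    the predictive-model table.
    """
    _check_counts(successes, n)
    z = sps.norm.ppf(1 - (1 - level) / 2)
    p = successes / n
    if successes == 0:
        lo = 0.0
    else:
        lo = ((2 * n * p + z * z
               - (z * math.sqrt(z * z - 1 / n + 4 * n * p * (1 - p) + (4 * p - 2)) + 1))
              / (2 * (n + z * z)))
    if successes == n:
        hi = 1.0
    else:
        hi = ((2 * n * p + z * z
               + (z * math.sqrt(z * z - 1 / n + 4 * n * p * (1 - p) - (4 * p - 2)) + 1))
              / (2 * (n + z * z)))
    return BinomialCI(successes, n, level, max(lo, 0.0), min(hi, 1.0))


def _check_counts(successes: int, n: int) -> None:
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes {successes} outside [0, {n}]")
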
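"""Hypothesis tests and interval estimators against formula oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from burncohort import (anova_dunnett, fisher_exact_2x2, mann_whitney,
                        t_test_equal_var, t_test_from_summary, wilson_ci,
                        wilson_ci_cc)


def pooled_t_oracle(x, y):
    """Textbook pooled-variance t-test, written out directly."""
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) \
        / (n1 + n2 - 2)
    t = (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
    return t, p


class TestTTest:
    def test_identical_samples_null(self):
        r = t_test_equal_var([1.0, 2, 3], [1.0, 2, 3])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_two_tailed == pytest.approx(1.0)

    def test_extreme_separation(self):
        r = t_test_equal_var([1.0, 2, 3], [101.0, 102, 103])
        assert r.p_two_tailed < 1e-6

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(3, 20))
            y = rng.normal(0.5, 2, rng.integers(3, 20))
            r = t_test_equal_var(x, y)
            t, p = pooled_t_oracle(x, y)
            assert r.statistic == pytest.approx(t, abs=1e-12)
            assert r.p_two_tailed == pytest.approx(p, abs=1e-12)

    def test_summary_form_equals_raw_form(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(0, 1, 9), rng.normal(1, 1, 12)
        raw = t_test_equal_var(x, y)
        summ = t_test_from_summary(x.mean(), x.std(ddof=1), len(x),
                                   y.mean(), y.std(ddof=1), len(y))
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-12)
        assert summ.p_two_tailed == pytest.approx(raw.p_two_tailed, abs=1e-12)

    def test_equal_means_null(self):
        r = t_test_from_summary(5.0, 1.0, 10, 5.0, 2.0, 10)
        assert r.statistic == 0.0 and r.p_two_tailed == pytest.approx(1.0)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            t_test_equal_var([1.0, 1.0], [2.0, 2.0])


class TestMannWhitney:
    def test_exact_enumeration_small_samples(self):
        # U = 0; 2 of the C(4,2) = 6 assignments are as extreme
        r = mann_whitney([1, 2], [3, 4])
        assert r.statistic == 0
        assert r.exact
        assert r.p_two_tailed == pytest.approx(1 / 3)

    def test_tied_duplicates_give_p_one(self):
        n = 3
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(n * n / 2)
        assert r.p_two_tailed == pytest.approx(1.0)
        assert not r.exact  # ties force the approximation

    def test_large_shifted_samples(self):
        rng = np.random.default_rng(17)
        r = mann_whitney(rng.normal(0, 1, 30), rng.normal(3, 1, 30))
        assert r.p_two_tailed < 0.001
        assert not r.exact

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError, match="ties"):
            mann_whitney([1, 1], [1, 2], method="exact")


class TestFisher:
    def test_strong_association(self):
        assert fisher_exact_2x2([[3, 14], [15, 2]]).p_two_tailed < 0.0001

    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_two_tailed == pytest.approx(1.0)

    def test_zero_margin_degenerate(self):
        assert fisher_exact_2x2([[0, 0], [5, 5]]).p_two_tailed == pytest.approx(1.0)

    def test_invariance_to_transpose_and_double_swap(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            t = rng.integers(0, 12, (2, 2))
            p = fisher_exact_2x2(t).p_two_tailed
            assert fisher_exact_2x2(t.T).p_two_tailed == pytest.approx(p)
            assert fisher_exact_2x2(t[::-1, ::-1]).p_two_tailed == pytest.approx(p)


def dunnett_mc_oracle(groups, ref, n_draws=200_000, seed=0):
    """Monte-Carlo Dunnett adjusted p-values from the equicorrelated
    multivariate-t maximum statistic."""
    rng = np.random.default_rng(seed)
    groups = [np.asarray(g, float) for g in groups]
    n0 = len(groups[ref])
    others = [g for i, g in enumerate(groups) if i != ref]
    idx = [i for i in range(len(groups)) if i != ref]
    df = sum(len(g) for g in groups) - len(groups)
    sp2 = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups) / df
    tstats = [(g.mean() - groups[ref].mean())
              / math.sqrt(sp2 * (1 / len(g) + 1 / n0)) for g in others]
    lam = np.array([math.sqrt(len(g) / (len(g) + n0)) for g in others])
    z0 = rng.standard_normal(n_draws)
    zi = rng.standard_normal((n_draws, len(others)))
    z = lam * z0[:, None] + np.sqrt(1 - lam**2) * zi
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    tmax = np.max(np.abs(z), axis=1) / s
    return {i: float(np.mean(tmax >= abs(t))) for i, t in zip(idx, tstats)}


class TestDunnett:
    def test_identical_groups_null(self):
        r = anova_dunnett([[1.0, 2, 3]] * 3, 0)
        assert r.statistic == pytest.approx(0.0)
        assert all(p == pytest.approx(1.0) for p in r.adjusted_p.values())

    def test_two_groups_reduces_to_unadjusted_comparison(self):
        x, y = [1.0, 2, 3, 4], [2.0, 4, 5, 7]
        r = anova_dunnett([x, y], 0, seed=0)
        t = t_test_equal_var(x, y)
        assert r.adjusted_p[1] == pytest.approx(t.p_two_tailed, abs=1e-3)

    def test_shifted_group_detected_others_not(self):
        rng = np.random.default_rng(23)
        groups = [list(rng.normal(0, 1, 10)) for _ in range(3)]
        groups.append(list(rng.normal(5, 1, 10)))
        r = anova_dunnett(groups, 0, seed=1)
        assert r.adjusted_p[3] < 0.001
        assert r.adjusted_p[1] > 0.5 and r.adjusted_p[2] > 0.5

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(29)
        groups = [list(rng.normal(m, 1, 8)) for m in (0, 0.8, 1.5, 0.2)]
        r = anova_dunnett(groups, 0, seed=2)
        mc = dunnett_mc_oracle(groups, 0, seed=3)
        for i in r.adjusted_p:
            assert r.adjusted_p[i] == pytest.approx(mc[i], abs=0.02)

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(31)
        groups = [list(rng.normal(m, 1, 7)) for m in (0, 0.5, 1.0)]
        r = anova_dunnett(groups, 0, seed=4)
        for i, adj in r.adjusted_p.items():
            unadj = t_test_equal_var(groups[i], groups[0]).p_two_tailed
            assert adj >= unadj - 2e-3

    def test_reference_index_out_of_range(self):
        with pytest.raises(ValueError):
            anova_dunnett([[1.0, 2], [3.0, 4]], 5)


class TestWilson:
    @pytest.mark.parametrize("k, n, lo2, hi2", [
        (14, 17, 0.56, 0.95),
        (11, 17, 0.39, 0.85),
        (15, 17, 0.62, 0.98),
        (12, 17, 0.44, 0.89),
    ])
    def test_continuity_corrected_bounds_at_two_decimals(self, k, n, lo2, hi2):
        ci = wilson_ci_cc(k, n)
        assert round(ci.lo, 2) == lo2
        assert round(ci.hi, 2) == hi2

    def test_zero_successes_clamped(self):
        ci = wilson_ci_cc(0, 10)
        assert ci.lo == 0.0
        assert 0 < ci.hi < 1

    def test_interval_contains_point_estimate_and_widens_plain_wilson(self):
        for n in (5, 17, 40):
            for k in range(n + 1):
                cc = wilson_ci_cc(k, n)
                assert cc.lo <= k / n <= cc.hi
                if 0 < k < n:
                    plain = wilson_ci(k, n)
                    assert cc.lo < plain.lo and cc.hi > plain.hi

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            wilson_ci_cc(5, 3)
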
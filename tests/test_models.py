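"""Firth logistic regression, AUROC, bootstrap, and the model table."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize

from burncohort import (auroc, bootstrap_auroc_ci, fit_prediction_models,
                        firth_logistic_fit, operating_point)
from burncohort.models import roc_table


def penalized_loglik_oracle(X, y, beta):
    """Jeffreys-penalized log-likelihood written out directly."""
    eta = X @ beta
    pi = 1 / (1 + np.exp(-eta))
    ll = np.sum(y * np.log(pi) + (1 - y) * np.log1p(-pi))
    W = pi * (1 - pi)
    info = X.T @ (X * W[:, None])
    return ll + 0.5 * np.linalg.slogdet(info)[1]


class TestFirth:
    def test_intercept_only_closed_form(self):
        # Jeffreys penalty adds 1/2 to each cell of the binomial count
        for k, n in [(0, 10), (3, 10), (10, 10)]:
            X = np.ones((n, 1))
            y = np.array([1.0] * k + [0.0] * (n - k))
            fit = firth_logistic_fit(X, y, tol=1e-10)
            expected = math.log((k + 0.5) / (n - k + 0.5))
            assert fit.converged
            assert fit.beta[0] == pytest.approx(expected, abs=1e-8)

    def test_complete_separation_finite_and_matches_nelder_mead(self):
        X = np.column_stack([np.ones(4), [0.0, 0, 1, 1]])
        y = np.array([0.0, 0, 1, 1])
        fit = firth_logistic_fit(X, y)
        assert fit.converged and np.all(np.isfinite(fit.beta))
        res = minimize(lambda b: -penalized_loglik_oracle(X, y, b),
                       x0=np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10,
                                "maxiter": 10_000})
        assert fit.beta == pytest.approx(res.x, abs=1e-4)

    def test_small_datasets_match_nelder_mead(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            n = 4
            X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
            y = rng.integers(0, 2, n).astype(float)
            fit = firth_logistic_fit(X, y, tol=1e-10, max_iter=1000)
            res = minimize(lambda b: -penalized_loglik_oracle(X, y, b),
                           x0=fit.beta + rng.normal(0, 0.1, 2),
                           method="Nelder-Mead",
                           options={"xatol": 1e-9, "fatol": 1e-11,
                                    "maxiter": 20_000})
            assert fit.beta == pytest.approx(res.x, abs=1e-4)

    def test_parameter_recovery_large_sample(self):
        # the Jeffreys penalty vanishes asymptotically
        rng = np.random.default_rng(43)
        beta_true = np.array([-1.0, 0.8])
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        fit = firth_logistic_fit(X, y)
        for b, t, se in zip(fit.beta, beta_true, fit.se):
            assert abs(b - t) < 3 * se

    def test_optimum_beats_origin_and_score_is_small(self):
        rng = np.random.default_rng(47)
        X = np.column_stack([np.ones(30), rng.normal(0, 1, 30)])
        y = rng.integers(0, 2, 30).astype(float)
        fit = firth_logistic_fit(X, y)
        assert fit.penalized_loglik >= penalized_loglik_oracle(X, y, np.zeros(2))

    def test_rank_deficient_design_names_columns(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="collinear"):
            firth_logistic_fit(X, np.array([0, 1, 0, 1, 0, 1.0]))


class TestAuroc:
    def test_four_point_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_bruteforce_pair_counting(self):
        rng = np.random.default_rng(53)
        for _ in range(30):
            n = 12
            scores = rng.choice([0.1, 0.2, 0.3, 0.4, 0.5], n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            expected = np.mean([
                1.0 if a > b else 0.5 if a == b else 0.0
                for a, b in itertools.product(pos, neg)])
            assert auroc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])


class TestBootstrap:
    def test_separated_data_degenerate_interval(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5, int), np.ones(5, int)]
        assert bootstrap_auroc_ci(scores, labels, 500, seed=0) == (1.0, 1.0)

    def test_bitwise_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(59)
        scores = rng.normal(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        labels[:2], labels[-2:] = 0, 1
        a = bootstrap_auroc_ci(scores, labels, 1000, seed=42)
        b = bootstrap_auroc_ci(scores, labels, 1000, seed=42)
        assert a == b

    def test_interval_narrows_with_sample_size(self):
        rng = np.random.default_rng(61)
        widths = []
        for n in (17, 170):
            pos = rng.normal(1, 1, n)
            neg = rng.normal(0, 1, n)
            scores = np.r_[pos, neg]
            labels = np.r_[np.ones(n, int), np.zeros(n, int)]
            lo, hi = bootstrap_auroc_ci(scores, labels, 2000, seed=7)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_interval_brackets_point_estimate(self, frame):
        scores = -frame["ratio"].to_numpy()
        labels = frame["hypersusceptible"].to_numpy().astype(int)
        lo, hi = bootstrap_auroc_ci(scores, labels, 2000, seed=11)
        a = auroc(scores, labels)
        assert lo - 0.02 <= a <= hi + 0.02


class TestOperatingPoint:
    def test_separated_data_perfect(self):
        thr, sens, spec, sci, pci = operating_point([1, 2, 8, 9], [0, 0, 1, 1])
        assert sens == 1.0 and spec == 1.0
        assert 2 < thr < 8

    def test_youden_by_exhaustive_scan(self):
        rng = np.random.default_rng(67)
        for _ in range(20):
            scores = rng.choice(np.linspace(0, 1, 7), 14)
            labels = rng.integers(0, 2, 14)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            best = max(
                (np.mean(pos >= t) + np.mean(neg < t) - 1, np.mean(pos >= t))
                for t in np.r_[scores, scores - 1e-9, scores.max() + 1])
            _, sens, spec, *_ = operating_point(scores, labels)
            assert sens + spec - 1 == pytest.approx(best[0], abs=1e-12)
            assert sens == pytest.approx(best[1], abs=1e-12)

    def test_wilson_cc_intervals_attached(self):
        # 14 of 17 correct in each class reproduces the (0.56, 0.95) band
        pos = np.r_[np.ones(14), np.zeros(3)]
        neg = np.r_[np.zeros(14), np.ones(3)]
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(17, int), np.zeros(17, int)]
        thr, sens, spec, sci, pci = operating_point(scores, labels)
        assert sens == pytest.approx(14 / 17)
        assert (round(sci.lo, 2), round(sci.hi, 2)) == (0.56, 0.95)
        assert (round(pci.lo, 2), round(pci.hi, 2)) == (0.56, 0.95)


@pytest.fixture(scope="module")
def results(frame):
    return fit_prediction_models(frame, n_boot=500, seed=5)


class TestModelTable:
    def test_nine_models_fitted(self, results):
        table = roc_table(results)
        assert len(table) == 9
        assert table["model"].tolist()[0] == "ratio"

    def test_ratio_slope_negative_and_discriminative(self, results):
        ratio_model = results[0]
        assert ratio_model.fit.beta[1] < 0  # lower ratio marks cases
        assert ratio_model.auroc > 0.5

    def test_fitted_monotone_model_preserves_raw_auroc(self, frame, results):
        raw = auroc(-frame["ratio"].to_numpy(),
                    frame["hypersusceptible"].astype(int).to_numpy())
        assert results[0].auroc == pytest.approx(raw, abs=1e-12)

    def test_permuted_outcome_near_chance(self, frame):
        rng = np.random.default_rng(71)
        shuffled = frame.copy()
        shuffled["hypersusceptible"] = rng.permutation(
            frame["hypersusceptible"].to_numpy())
        res = fit_prediction_models(shuffled, n_boot=200, seed=3)
        for r in res:
            assert r.ci_lo - 0.05 <= 0.5 <= r.ci_hi + 0.05

    def test_combined_model_at_least_nested_single(self, frame):
        # the fit maximizes penalized likelihood, not AUROC, so small
        # in-sample inversions of the nesting inequality occur
        eps = 0.06
        for seed in range(3):
            from burncohort import generate_cohort, build_analysis_frame
            patients, infections = generate_cohort(seed=seed + 100)
            f = build_analysis_frame(patients, infections)
            res = {r.model: r.auroc
                   for r in fit_prediction_models(f, n_boot=10, seed=seed)}
            for score in ("tbsa", "apacheii", "baux", "rbaux"):
                assert res[f"ratio+{score}"] >= max(res["ratio"],
                                                    res[score]) - eps
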
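import numpy as np
import pytest

from placebo_enrich import (
    MetaDataset,
    MetaRegressionResult,
    adjusted_r2,
    estimate_tau2,
    fit_meta_regression,
    i_squared,
    predict,
    within_study_variance,
)
from placebo_enrich.meta_regression import _reml_nll


def random_dataset(rng, k=19, p=2, tau2=0.007):
    X = np.column_stack([np.ones(k)] + [rng.uniform(0, 6, k) for _ in range(p)])
    beta = rng.normal(0, 0.1, p + 1) + np.array([0.4] + [0.0] * p)
    v = rng.uniform(5e-4, 5e-3, k)
    y = X @ beta + rng.normal(0, np.sqrt(tau2), k) + rng.normal(0, np.sqrt(v))
    return MetaDataset(y=y, v=v, X=X)


class TestWithinStudyVariance:
    def test_interior_proportion(self):
        assert within_study_variance(50, 100) == pytest.approx(0.0025, abs=1e-15)

    def test_boundary_correction_at_zero_events(self):
        p_shrunk = 0.5 / 51  # (0 + 1/2) / (50 + 1)
        expected = p_shrunk * (1 - p_shrunk) / 50
        assert within_study_variance(0, 50) == pytest.approx(expected, abs=1e-15)
        assert expected == pytest.approx(1.942e-4, abs=1e-7)

    def test_typical_arm(self):
        assert within_study_variance(16, 97) == pytest.approx((16 / 97) * (81 / 97) / 97, abs=1e-15)
        assert within_study_variance(16, 97) == pytest.approx(0.00142, abs=1e-5)

    def test_errors(self):
        with pytest.raises(ValueError):
            within_study_variance(1, 0)
        with pytest.raises(ValueError):
            within_study_variance(5, 4)
        with pytest.raises(ValueError):
            within_study_variance(0, 50, correction="none")


class TestTau2MethodOfMoments:
    def test_toy_with_q_equal_to_df(self):
        data = MetaDataset(y=[0.1, 0.2, 0.3], v=[0.01] * 3, X=np.ones((3, 1)))
        # Q = 2 equals df = 2, so the moment estimate truncates to 0
        assert estimate_tau2(data, "mom") == pytest.approx(0.0, abs=1e-15)

    def test_toy_with_excess_heterogeneity(self):
        data = MetaDataset(y=[0.0, 0.2, 0.4], v=[0.01] * 3, X=np.ones((3, 1)))
        # Q = 8, df = 2, C = 200  ->  (8 - 2)/200 = 0.03
        assert estimate_tau2(data, "mom") == pytest.approx(0.03, abs=1e-12)

    def test_identical_outcomes_give_zero_for_both_methods(self):
        data = MetaDataset(y=[0.2] * 5, v=[0.01, 0.02, 0.03, 0.01, 0.05], X=np.ones((5, 1)))
        assert estimate_tau2(data, "mom") == 0.0
        assert estimate_tau2(data, "reml") == pytest.approx(0.0, abs=1e-10)


class TestTau2Reml:
    def test_matches_restricted_likelihood_grid(self):
        rng = np.random.default_rng(5150)
        for _ in range(5):
            data = random_dataset(rng, k=10, p=1, tau2=0.01)
            grid = np.arange(0.0, 0.5, 1e-5)
            nll = np.array([_reml_nll(t, data.y, data.X, data.v) for t in grid[::50]])
            coarse = grid[::50][np.argmin(nll)]
            fine = np.arange(max(0.0, coarse - 6e-4), coarse + 6e-4, 1e-6)
            nll_fine = np.array([_reml_nll(t, data.y, data.X, data.v) for t in fine])
            grid_argmax = fine[np.argmin(nll_fine)]
            assert estimate_tau2(data, "reml") == pytest.approx(grid_argmax, abs=2e-5)

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        data = random_dataset(rng)
        assert estimate_tau2(data, "reml") == estimate_tau2(data, "reml")


class TestGls:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(314)
        data = random_dataset(rng, k=19, p=2)
        result = fit_meta_regression(data)
        w = 1.0 / (data.v + result.tau2)
        # explicit weighted normal equations, solved independently
        W = np.diag(w)
        beta_oracle = np.linalg.solve(data.X.T @ W @ data.X, data.X.T @ W @ data.y)
        np.testing.assert_allclose(result.beta, beta_oracle, atol=1e-10, rtol=0)

    def test_reduces_to_ols_with_zero_heterogeneity_and_equal_v(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        y = 0.4 - 0.03 * np.arange(6.0)  # exactly linear: no residual heterogeneity
        data = MetaDataset(y=y, v=[0.002] * 6, X=X)
        result = fit_meta_regression(data)
        assert result.tau2 == pytest.approx(0.0, abs=1e-12)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(result.beta, beta_ols, atol=1e-10)

    def test_insufficient_studies(self):
        X = np.column_stack([np.ones(2), [1.0, 2.0]])
        with pytest.raises(ValueError, match="insufficient studies"):
            fit_meta_regression(MetaDataset(y=[0.1, 0.2], v=[0.01, 0.01], X=X))

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(5), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="rank"):
            MetaDataset(y=np.zeros(5), v=np.full(5, 0.01), X=X)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(99)
        data = random_dataset(rng, k=15, p=1)
        c = 3.7
        scaled = MetaDataset(y=c * data.y, v=c**2 * data.v, X=data.X)
        for method in ("reml", "mom"):
            r1 = fit_meta_regression(data, tau2_method=method)
            r2 = fit_meta_regression(scaled, tau2_method=method)
            np.testing.assert_allclose(r2.beta, c * r1.beta, rtol=1e-6)
            assert r2.tau2 == pytest.approx(c**2 * r1.tau2, rel=1e-5, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1234)
        data = random_dataset(rng, k=12, p=2)
        perm = rng.permutation(12)
        shuffled = MetaDataset(y=data.y[perm], v=data.v[perm], X=data.X[perm])
        r1, r2 = fit_meta_regression(data), fit_meta_regression(shuffled)
        np.testing.assert_allclose(r1.beta, r2.beta, atol=1e-12)
        assert r1.tau2 == pytest.approx(r2.tau2, abs=1e-12)
        assert r1.i2 == pytest.approx(r2.i2, abs=1e-12)

    def test_knapp_hartung_never_deflates(self):
        rng = np.random.default_rng(2)
        data = random_dataset(rng, k=19, p=2)
        plain = fit_meta_regression(data)
        kh = fit_meta_regression(data, knapp_hartung=True)
        assert np.all(kh.se >= plain.se - 1e-15)
        np.testing.assert_allclose(kh.beta, plain.beta, atol=1e-12)

    def test_t_versus_z_pvalues(self):
        rng = np.random.default_rng(3)
        data = random_dataset(rng, k=19, p=2)
        t_fit = fit_meta_regression(data, test="t")
        z_fit = fit_meta_regression(data, test="z")
        # the t reference is heavier-tailed: p-values are never smaller
        assert np.all(t_fit.pval >= z_fit.pval)


class TestHeterogeneitySummaries:
    def test_i2_zero_without_heterogeneity(self):
        assert i_squared(0.0, [0.01, 0.02, 0.03]) == 0.0

    def test_i2_equal_variances_closed_form(self):
        v = 0.004
        assert i_squared(0.007, [v] * 8, p=0) == pytest.approx(0.007 / (0.007 + v), abs=1e-12)

    def test_i2_consistent_with_printed_heterogeneity_pair(self):
        # tau2 = 0.007 over a typical within-study variance of 0.0013125
        # gives I2 = 0.84 at two decimals
        assert i_squared(0.007, [0.0013125] * 16, p=0) == pytest.approx(0.84, abs=0.0025)

    def test_i2_errors(self):
        with pytest.raises(ValueError):
            i_squared(0.007, [])
        with pytest.raises(ValueError):
            i_squared(0.007, [0.01], p=0)

    @pytest.mark.parametrize("null,model,expected", [
        (0.010, 0.007, 0.30), (0.007, 0.007, 0.0), (0.0, 0.0, 0.0),
    ])
    def test_adjusted_r2_values(self, null, model, expected):
        assert adjusted_r2(null, model) == pytest.approx(expected, abs=1e-12)

    def test_adjusted_r2_negative_when_model_inflates_tau2(self):
        assert adjusted_r2(0.010, 0.0106) == pytest.approx(-0.06, abs=1e-12)

    def test_adjusted_r2_sentinel(self):
        assert adjusted_r2(0.0, 0.01) == -np.inf


class TestPrediction:
    def make_result(self, beta, cov=None, df=16.0):
        beta = np.asarray(beta, dtype=float)
        cov = np.zeros((beta.size, beta.size)) if cov is None else np.asarray(cov)
        return MetaRegressionResult(
            beta=beta, se=np.sqrt(np.diag(cov)), stat=np.zeros_like(beta),
            pval=np.ones_like(beta), cov=cov, tau2=0.007, i2=0.84,
            adjusted_r2=None, tau2_null=None, k=19, p=beta.size - 1,
            term_names=[f"b{i}" for i in range(beta.size)],
            tau2_method="reml", test_method="t", knapp_hartung=False, df=df,
        )

    def test_basis_vector_returns_intercept(self):
        res = self.make_result([0.4438, -0.0256, -0.1987])
        assert predict(res, [1, 0, 0]).point == pytest.approx(0.4438)

    def test_interval_ordering(self):
        rng = np.random.default_rng(8)
        data = random_dataset(rng, k=19, p=2)
        result = fit_meta_regression(data)
        pred = predict(result, [1.0, 3.0, 1.0])
        assert pred.ci_low <= pred.point <= pred.ci_high

    def test_interval_widens_away_from_centroid(self):
        rng = np.random.default_rng(9)
        data = random_dataset(rng, k=19, p=1)
        result = fit_meta_regression(data)
        center = float(np.mean(data.X[:, 1]))
        near = predict(result, [1.0, center])
        far = predict(result, [1.0, center + 10.0])
        assert (far.ci_high - far.ci_low) > (near.ci_high - near.ci_low)

    def test_nonconformable_covariates(self):
        res = self.make_result([0.4, -0.02])
        with pytest.raises(ValueError, match="conform"):
            predict(res, [1.0, 3.0, 1.0])
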
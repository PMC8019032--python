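"""ZINB mixed model: likelihood kernels, Laplace fit, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beescape.zinb import (
    NonEstimableError,
    ParameterDomainError,
    ZinbData,
    aicc,
    collinearity_report,
    fit_zinb,
    joint_loglik,
    laplace_loglik,
    moran_i,
    nb_logpmf,
    simulate_response,
    simulated_residual_check,
    zero_inflation_check,
    zinb_logpmf,
)
from conftest import simulate_zinb_dataset
from oracles import zinb_logpmf_scalar


class TestLikelihoodKernels:
    def test_matches_scalar_mixture_oracle(self):
        """Vectorised ZINB log-pmf equals a term-by-term scalar computation
        of the mixture on a 5-row dataset."""
        y = np.array([0, 3, 0, 12, 1])
        mu = np.array([0.5, 2.0, 8.0, 10.0, 1.3])
        theta, pi = 1.7, 0.22
        got = zinb_logpmf(y, mu, theta, pi)
        want = [zinb_logpmf_scalar(int(yi), mi, theta, pi) for yi, mi in zip(y, mu)]
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_pi_zero_reduces_to_nb(self):
        y = np.arange(6)
        mu = np.linspace(0.5, 9, 6)
        np.testing.assert_allclose(
            zinb_logpmf(y, mu, 2.0, 0.0), nb_logpmf(y, mu, 2.0), rtol=1e-12
        )

    def test_large_theta_poisson_limit(self):
        """theta -> 1e6 with pi=0 approaches the Poisson log-likelihood."""
        rng = np.random.default_rng(5)
        y = rng.poisson(4.0, size=10)
        mu = np.full(10, 4.0)
        nb = nb_logpmf(y, mu, 1e6).sum()
        pois = stats.poisson.logpmf(y, mu).sum()
        assert nb == pytest.approx(pois, abs=1e-4)

    @pytest.mark.parametrize("theta,pi", [(-1.0, 0.1), (1.0, 1.0), (1.0, -0.1)])
    def test_parameter_domain(self, theta, pi):
        with pytest.raises(ParameterDomainError):
            zinb_logpmf(np.array([0, 1]), np.array([1.0, 1.0]), theta, pi)

    def test_joint_loglik_collapses_without_zero_inflation(self):
        data, beta = simulate_zinb_dataset(0, n_sites=3, n_periods=2, per_cell=4)
        u = np.array([0.1, -0.2, 0.05])
        v = np.array([0.0, 0.3])
        ll_mix = joint_loglik(data, beta, 1.5, 0.0, 0.3, 0.2, u, v)
        # manual: NB loglik + Gaussian priors
        eta = data.X @ beta + data.offset + u[data.site_idx] + v[data.period_idx]
        manual = (
            nb_logpmf(data.y, np.exp(eta), 1.5).sum()
            + stats.norm.logpdf(u, scale=np.sqrt(0.3)).sum()
            + stats.norm.logpdf(v, scale=np.sqrt(0.2)).sum()
        )
        assert ll_mix == pytest.approx(manual, rel=1e-12)


class TestLaplace:
    def test_invariance_to_row_order_and_level_labels(self):
        data, beta = simulate_zinb_dataset(3, n_sites=4, n_periods=3, per_cell=5)
        ll, _ = laplace_loglik(data, beta, 1.5, 0.1, 0.3, 0.2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(data.y))
        site_relab = rng.permutation(data.n_sites)
        shuffled = ZinbData(
            y=data.y[perm],
            X=data.X[perm],
            offset=data.offset[perm],
            site_idx=site_relab[data.site_idx[perm]],
            period_idx=data.period_idx[perm],
            term_names=data.term_names,
        )
        ll2, _ = laplace_loglik(shuffled, beta, 1.5, 0.1, 0.3, 0.2)
        assert ll2 == pytest.approx(ll, abs=1e-6)

    def test_offset_scaling_contract(self):
        """Adding c to the offset multiplies mu by e^c at fixed beta, and a
        refit moves only the intercept (by −c), leaving slopes, fitted
        means and the maximised log-likelihood unchanged."""
        data, beta = simulate_zinb_dataset(11, n_sites=5, n_periods=3, per_cell=6)
        c = 0.7
        shifted = ZinbData(
            y=data.y,
            X=data.X,
            offset=data.offset + c,
            site_idx=data.site_idx,
            period_idx=data.period_idx,
            term_names=data.term_names,
        )
        mu0 = np.exp(data.X @ beta + data.offset)
        mu1 = np.exp(shifted.X @ beta + shifted.offset)
        np.testing.assert_allclose(mu1, np.exp(c) * mu0, rtol=1e-12)
        f0 = fit_zinb(data, random_effects=False)
        f1 = fit_zinb(shifted, random_effects=False)
        assert f1.beta[0] == pytest.approx(f0.beta[0] - c, abs=2e-3)
        np.testing.assert_allclose(f1.beta[1:], f0.beta[1:], atol=2e-3)
        assert f1.loglik == pytest.approx(f0.loglik, abs=1e-4)


class TestFit:
    def test_no_random_effect_reduction_matches_statsmodels(self):
        """With random effects disabled the fit agrees with an independent
        fixed-effects ZINB implementation to 1e-3."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 600
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        offset = np.full(n, np.log(30.0))
        mu = np.exp(X @ [0.5, 0.8] + offset)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        y = np.where(rng.random(n) < 0.2, 0, y)
        data = ZinbData(
            y=y,
            X=X,
            offset=offset,
            site_idx=np.zeros(n, dtype=int),
            period_idx=np.zeros(n, dtype=int),
            term_names=("(Intercept)", "x"),
        )
        fit = fit_zinb(data, random_effects=False)
        sm_fit = sm.ZeroInflatedNegativeBinomialP(
            y, X, exog_infl=np.ones((n, 1)), offset=offset, p=2
        ).fit(disp=0, maxiter=500, method="bfgs")
        np.testing.assert_allclose(fit.beta, sm_fit.params[1:3], atol=1e-3)
        assert fit.theta == pytest.approx(1 / sm_fit.params[-1], rel=1e-3)
        assert fit.pi == pytest.approx(
            float(1 / (1 + np.exp(-sm_fit.params[0]))), abs=1e-3
        )
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-3)

    def test_intercept_only_nb_closed_form(self):
        """Intercept-only NB with pi=0 and a constant offset: the ML
        intercept is log(mean y) − offset (the offset-adjusted mean)."""
        rng = np.random.default_rng(9)
        n = 400
        offset = np.full(n, np.log(30.0))
        mu = np.exp(0.8 + offset)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        data = ZinbData(
            y=y,
            X=np.ones((n, 1)),
            offset=offset,
            site_idx=np.zeros(n, dtype=int),
            period_idx=np.zeros(n, dtype=int),
            term_names=("(Intercept)",),
        )
        fit = fit_zinb(data, random_effects=False, zero_inflated=False)
        closed = np.log(y.sum() / np.exp(offset).sum())
        assert fit.beta[0] == pytest.approx(closed, abs=1e-5)

    def test_mixed_fit_recovers_truth_within_3se(self):
        data, beta = simulate_zinb_dataset(21)
        fit = fit_zinb(data)
        assert fit.converged
        # slope estimate within 3 SE of truth (intercept confounds with
        # the realised random-intercept means)
        assert abs(fit.beta[1] - beta[1]) < 3 * fit.se[1]
        assert fit.theta > 0 and 0 <= fit.pi < 1
        assert fit.sigma2_site >= 0 and fit.sigma2_period >= 0

    def test_all_zero_response_non_estimable(self):
        data, _ = simulate_zinb_dataset(2, n_sites=3, n_periods=2, per_cell=4)
        data.y = np.zeros_like(data.y)
        with pytest.raises(NonEstimableError):
            fit_zinb(data)


class TestAicc:
    def test_direct_formula(self):
        assert aicc(-100.0, 3, 30) == pytest.approx(206 + 24 / 26)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100.0, 3, 10**9) == pytest.approx(206.0, abs=1e-6)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestZeroInflationCheck:
    def test_pure_nb_ratio_near_one(self):
        data, _ = simulate_zinb_dataset(31, pi=0.0, per_cell=30)
        fit = fit_zinb(data, zero_inflated=False)
        ratio = zero_inflation_check(data, fit)
        assert 0.8 < ratio < 1.25

    def test_structural_zeros_inflate_ratio(self):
        """Injecting 50% structural zeros into NB data roughly doubles the
        observed/expected zero ratio judged against the clean-data NB fit:
        observed ≈ 0.5 + 0.5·p0 while expected stays p0."""
        data, _ = simulate_zinb_dataset(32, pi=0.0, per_cell=30)
        fit = fit_zinb(data, zero_inflated=False)
        p0 = zero_inflation_check(data, fit) ** -1 * (data.y == 0).mean()
        rng = np.random.default_rng(1)
        inflated = ZinbData(
            y=np.where(rng.random(len(data.y)) < 0.5, 0, data.y),
            X=data.X,
            offset=data.offset,
            site_idx=data.site_idx,
            period_idx=data.period_idx,
            term_names=data.term_names,
        )
        ratio = zero_inflation_check(inflated, fit)
        assert ratio == pytest.approx((0.5 + 0.5 * p0) / p0, rel=0.12)
        assert ratio > 1.5


class TestSimulatedResiduals:
    def test_well_specified_model_passes(self):
        data, _ = simulate_zinb_dataset(41, n_sites=6, n_periods=3, per_cell=10)
        fit = fit_zinb(data)
        out = simulated_residual_check(fit, data, n_sim=250, seed=1)
        assert not out["flagged"]

    def test_gross_misspecification_flagged(self):
        """A rounded heavy-tailed lognormal response is not ZINB; the
        randomized-quantile residuals should fail uniformity."""
        rng = np.random.default_rng(51)
        n = 500
        y = np.round(np.exp(rng.normal(0.0, 2.5, size=n))).astype(int)
        X = np.ones((n, 1))
        data = ZinbData(
            y=y,
            X=X,
            offset=np.zeros(n),
            site_idx=np.zeros(n, dtype=int),
            period_idx=np.zeros(n, dtype=int),
            term_names=("(Intercept)",),
        )
        fit = fit_zinb(data, random_effects=False)
        out = simulated_residual_check(fit, data, n_sim=250, seed=2)
        assert out["flagged"]

    def test_refuses_unconverged(self):
        data, _ = simulate_zinb_dataset(42, n_sites=6, n_periods=3, per_cell=10)
        fit = fit_zinb(data)
        fit.converged = False
        with pytest.raises(NonEstimableError):
            simulated_residual_check(fit, data)


class TestCollinearity:
    def test_orthogonal_columns_unit_vif(self):
        n = 64
        t = np.arange(n)
        design = pd.DataFrame(
            {
                "a": np.cos(2 * np.pi * t / n),
                "b": np.sin(2 * np.pi * t / n),
                "c": np.cos(4 * np.pi * t / n),
            }
        )
        rep = collinearity_report(design)
        assert np.allclose(rep["vif"].to_numpy(), 1.0, atol=1e-9)

    def test_duplicated_column_infinite_vif(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        rep = collinearity_report(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)}))
        assert np.isinf(rep["vif"]["a"]) and np.isinf(rep["vif"]["b"])

    def test_matches_bruteforce_regression(self, rng):
        X = rng.normal(size=(80, 4))
        X[:, 3] = 0.6 * X[:, 0] + 0.4 * X[:, 1] + 0.3 * rng.normal(size=80)
        design = pd.DataFrame(X, columns=list("abcd"))
        rep = collinearity_report(design)
        import statsmodels.api as sm

        for j, name in enumerate(design.columns):
            others = sm.add_constant(np.delete(X, j, axis=1))
            r2 = sm.OLS(X[:, j], others).fit().rsquared
            assert rep["vif"][name] == pytest.approx(1 / (1 - r2), rel=1e-8)


class TestMoranI:
    def test_expected_value_closed_form(self, rng):
        for n in (5, 12, 30):
            vals = rng.normal(size=n)
            coords = rng.uniform(0, 100, size=(n, 2))
            out = moran_i(vals, coords)
            assert out["expected"] == pytest.approx(-1 / (n - 1))

    def test_matches_definition_oracle(self, rng):
        from oracles import moran_i_definition

        vals = rng.normal(size=15)
        coords = rng.uniform(0, 1000, size=(15, 2))
        out = moran_i(vals, coords)
        assert out["I"] == pytest.approx(moran_i_definition(vals, coords), rel=1e-10)

    def test_spatial_gradient_detected(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 1000, size=(27, 2))
        vals = coords[:, 0] / 100.0 + rng.normal(0, 0.3, 27)
        out = moran_i(vals, coords)
        assert out["I"] > out["expected"]
        assert out["p"] < 0.05

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 1000, size=(27, 2))
        rejections = 0
        reps = 400
        for _ in range(reps):
            vals = rng.normal(size=27)
            if moran_i(vals, coords)["p"] < 0.05 :
                rejections += 1
        rate = rejections / reps
        assert 0.01 < rate < 0.10

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            moran_i(np.ones(5), np.random.default_rng(0).uniform(size=(5, 2)))
        coords = np.zeros((4, 2))
        with pytest.raises(ValueError):
            moran_i(np.arange(4.0), coords)
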
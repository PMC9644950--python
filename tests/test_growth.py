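"""Age interpolation, Gompertz growth curves, beta regression, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from osteovasc import growth as gr
from osteovasc.errors import (DegenerateInputError, FitFailureError,
                              OutOfRangeError)


class TestInterpolateAge:
    anchors = gr.MassAgeAnchors(ages=(1.0, 42.0), masses=(50.0, 2000.0))

    def test_anchor_masses_map_to_anchor_ages(self):
        assert gr.interpolate_age(50.0, self.anchors) == pytest.approx(1.0)
        assert gr.interpolate_age(2000.0, self.anchors) == pytest.approx(42.0)

    def test_halfway_mass_gives_halfway_age(self):
        assert gr.interpolate_age(1025.0, self.anchors) == pytest.approx(21.5)

    def test_no_extrapolation(self):
        with pytest.raises(OutOfRangeError):
            gr.interpolate_age(2500.0, self.anchors)
        with pytest.raises(OutOfRangeError):
            gr.interpolate_age(10.0, self.anchors)

    @given(st.floats(50.0, 2000.0), st.floats(50.0, 2000.0))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_mass(self, m1, m2):
        a1 = gr.interpolate_age(m1, self.anchors)
        a2 = gr.interpolate_age(m2, self.anchors)
        assert (m1 <= m2) == (a1 <= a2)

    def test_invalid_anchors(self):
        with pytest.raises(ValueError):
            gr.MassAgeAnchors(ages=(42.0, 1.0), masses=(50.0, 2000.0))


class TestGompertz:
    def test_noise_free_recovery(self):
        t = np.linspace(0, 60, 25)
        y = gr.gompertz(t, 100.0, 4.0, 0.1)
        fit = gr.fit_gompertz(t, y)
        assert abs(fit.A - 100.0) / 100.0 < 1e-4
        assert abs(fit.b - 4.0) / 4.0 < 1e-4
        assert abs(fit.k - 0.1) / 0.1 < 1e-4

    def test_noisy_median_bias_below_2pct(self):
        """200 replicate fits at noise sd = 2% of the asymptote, n = 30."""
        t = np.linspace(0, 60, 30)
        y0 = gr.gompertz(t, 100.0, 4.0, 0.1)
        rng = np.random.default_rng(1)
        rel = []
        for _ in range(200):
            y = np.clip(y0 + rng.normal(0, 2.0, size=30), 1e-3, None)
            f = gr.fit_gompertz(t, y, n_restarts=3)
            rel.append([(f.A - 100) / 100, (f.b - 4) / 4, (f.k - 0.1) / 0.1])
        med = np.median(np.asarray(rel), axis=0)
        assert np.all(np.abs(med) < 0.02)

    def test_inflection_closed_form_matches_grid_argmax(self):
        fit = gr.GompertzFit(A=100.0, b=4.0, k=0.1, cov=np.eye(3), n=10, rss=0.0)
        tt = np.linspace(0.0, 80.0, 160_001)
        rate = fit.rate(tt)
        assert abs(tt[np.argmax(rate)] - np.log(4.0) / 0.1) < 1e-3
        assert fit.t_infl == pytest.approx(np.log(4.0) / 0.1)
        assert fit.max_rate == pytest.approx(100.0 * 0.1 / np.e)
        assert rate.max() == pytest.approx(fit.max_rate, rel=1e-6)

    def test_rate_nonnegative_and_vanishes(self):
        fit = gr.GompertzFit(A=50.0, b=3.0, k=0.2, cov=np.eye(3), n=10, rss=0.0)
        tt = np.linspace(0, 200, 500)
        assert np.all(fit.rate(tt) >= 0)
        assert fit.rate(1e6) == pytest.approx(0.0, abs=1e-12)

    def test_constant_data_degenerate(self):
        t = np.linspace(0, 10, 8)
        with pytest.raises(FitFailureError):
            gr.fit_gompertz(t, np.full(8, 5.0))

    def test_too_few_ages(self):
        with pytest.raises(ValueError):
            gr.fit_gompertz([1, 2, 3], [1, 2, 3])

    def test_multistart_never_worse_than_deterministic_start(self):
        """Multi-start refinement cannot increase the residual sum of squares."""
        rng = np.random.default_rng(5)
        t = np.linspace(0, 50, 20)
        y = np.clip(gr.gompertz(t, 80.0, 5.0, 0.12) + rng.normal(0, 1.5, 20), 0.05, None)
        single = gr.fit_gompertz(t, y, n_restarts=0)
        multi = gr.fit_gompertz(t, y, n_restarts=10)
        assert multi.rss <= single.rss + 1e-9

    def test_fitted_curve_monotone(self):
        t = np.linspace(0, 60, 25)
        y = gr.gompertz(t, 100.0, 4.0, 0.1)
        fit = gr.fit_gompertz(t, y)
        tt = np.linspace(0, 100, 400)
        assert np.all(np.diff(fit.predict(tt)) >= 0)

    def test_confidence_band_contains_curve(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 60, 30)
        y = gr.gompertz(t, 100.0, 4.0, 0.1) + rng.normal(0, 2, 30)
        fit = gr.fit_gompertz(t, y)
        lo, hi = fit.confidence_band(t)
        yhat = fit.predict(t)
        assert np.all(lo <= yhat) and np.all(yhat <= hi)


class TestBetaRegression:
    def test_noise_free_limit_pseudo_r2(self):
        """logit(y) exactly affine in x at very high precision: pseudo-R2
        approaches 1."""
        rng = np.random.default_rng(0)
        x = np.linspace(-2, 2, 100)
        mu = 1 / (1 + np.exp(-(0.3 + 0.9 * x)))
        y = rng.beta(mu * 1e4, (1 - mu) * 1e4)
        fit = gr.fit_beta_regression(y, np.column_stack([np.ones_like(x), x]))
        assert fit.pseudo_r2 >= 0.999

    def test_intercept_only_matches_grid_search_ml(self):
        """1D maximum-likelihood oracle by grid search over (mu, phi)."""
        rng = np.random.default_rng(2)
        y = rng.beta(0.3 * 30, 0.7 * 30, size=200)
        fit = gr.fit_beta_regression(y, np.ones((200, 1)))
        mu_hat = 1 / (1 + np.exp(-fit.beta[0]))

        mus = np.linspace(0.2, 0.4, 201)
        phis = np.linspace(5, 80, 151)
        M, P = np.meshgrid(mus, phis, indexing="ij")
        ll = stats.beta.logpdf(y[None, None, :], (M * P)[..., None],
                               ((1 - M) * P)[..., None]).sum(-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert abs(mu_hat - mus[i]) < 1e-3
        assert fit.loglik >= ll[i, j] - 1e-6  # ML beats the grid optimum

    def test_parameter_recovery_within_3_sigma(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 60, size=500)
        X = np.column_stack([np.ones_like(x), x])
        eta = -1.0 + 0.05 * x
        mu = 1 / (1 + np.exp(-eta))
        y = rng.beta(mu * 50, (1 - mu) * 50)
        fit = gr.fit_beta_regression(y, X)
        delta = fit.beta - np.array([-1.0, 0.05])
        wald = delta @ np.linalg.solve(fit.cov_beta, delta)
        assert wald <= stats.chi2.ppf(0.9973, 2)

    def test_optimality_on_simulated_data(self):
        """ML log-likelihood is at least the log-likelihood at the true
        simulated parameters."""
        rng = np.random.default_rng(4)
        x = np.linspace(-1, 1, 120)
        mu = 1 / (1 + np.exp(-(0.2 + 0.7 * x)))
        y = rng.beta(mu * 40, (1 - mu) * 40)
        fit = gr.fit_beta_regression(y, np.column_stack([np.ones_like(x), x]))
        ll_true = stats.beta.logpdf(y, mu * 40, (1 - mu) * 40).sum()
        assert fit.loglik >= ll_true - 1e-6

    def test_pseudo_r2_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 150)
        mu = 1 / (1 + np.exp(-(0.1 + 0.2 * x)))
        y = rng.beta(mu * 30, (1 - mu) * 30)
        f1 = gr.fit_beta_regression(y, np.column_stack([np.ones_like(x), x]))
        f2 = gr.fit_beta_regression(y, np.column_stack([np.ones_like(x), 100 * x + 7]))
        assert f1.pseudo_r2 == pytest.approx(f2.pseudo_r2, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gr.fit_beta_regression([0.2, 1.4, 0.5], np.ones((3, 1)))
        X = np.ones((10, 2))  # duplicated column: rank deficient
        with pytest.raises(ValueError):
            gr.fit_beta_regression(np.full(10, 0.4), X)

    def test_boundary_values_shrunk(self):
        y = np.array([0.0, 0.2, 0.5, 0.9, 1.0] * 4)
        fit = gr.fit_beta_regression(y, np.ones((20, 1)))
        assert np.isfinite(fit.loglik)


class TestLRTest:
    def test_model_vs_itself_needs_nesting(self):
        rng = np.random.default_rng(6)
        y = rng.beta(12, 18, size=50)
        fit = gr.fit_beta_regression(y, np.ones((50, 1)))
        with pytest.raises(ValueError):
            gr.lr_test(fit, fit)

    def test_identical_loglik_gives_p_one(self):
        a = gr.BetaRegFit(beta=np.zeros(2), phi=10.0, loglik=-5.0,
                          eta=np.zeros(4), pseudo_r2=0.0, n_params=3, nobs=4)
        b = gr.BetaRegFit(beta=np.zeros(1), phi=10.0, loglik=-5.0,
                          eta=np.zeros(4), pseudo_r2=0.0, n_params=2, nobs=4)
        res = gr.lr_test(a, b)
        assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_power_at_simulated_effect_size(self):
        """Porosity generated logit-linear in growth rate at cohort-like
        sample size: the LR test rejects in at least 90% of 100 replicates."""
        rng = np.random.default_rng(11)
        n = 18
        rate = rng.uniform(0.0, 0.12, size=n)  # mm/day, radial-growth scale
        X = np.column_stack([np.ones(n), rate])
        X0 = np.ones((n, 1))
        mu = 1 / (1 + np.exp(-(-3.0 + 13.0 * rate)))
        hits = 0
        for _ in range(100):
            y = rng.beta(mu * 60, (1 - mu) * 60)
            full = gr.fit_beta_regression(y, X)
            null = gr.fit_beta_regression(y, X0)
            if gr.lr_test(full, null).pvalue < 0.05:
                hits += 1
        assert hits >= 90

    def test_statistic_nonnegative_on_null_data(self):
        rng = np.random.default_rng(7)
        x = np.linspace(-1, 1, 60)
        X = np.column_stack([np.ones_like(x), x])
        for _ in range(20):
            y = rng.beta(0.4 * 25, 0.6 * 25, size=60)
            full = gr.fit_beta_regression(y, X)
            null = gr.fit_beta_regression(y, np.ones((60, 1)))
            assert gr.lr_test(full, null).statistic >= 0.0


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = gr.pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = gr.pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            gr.pearson_r([1, 2, 3], [5, 5, 5])

    def test_p_value_matches_permutation_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = 0.8 * x + rng.normal(size=10)
        r, p = gr.pearson_r(x, y)
        n_perm = 20_000
        more_extreme = 0
        for _ in range(n_perm):
            rp = np.corrcoef(x, rng.permutation(y))[0, 1]
            if abs(rp) >= abs(r):
                more_extreme += 1
        p_perm = more_extreme / n_perm
        assert abs(p - p_perm) < 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01
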
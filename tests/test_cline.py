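"""Sigmoid cline model: closed forms, likelihood, ML fitting, LRT, residuals."""

import numpy as np
import pytest

from wavecline.cline import (
    ClineParams,
    cline_fraction,
    cline_mean,
    cline_sd,
    fit_cline,
    fit_null,
    likelihood_ratio_test,
    neg_log_likelihood,
    residuals,
)

PARAMS = ClineParams(centre=40.0, width=15.0, mu_crab=1.0, mu_wave=3.0,
                     sd_crab=0.3, sd_wave=0.3, sd_hybrid=0.2)


class TestClineFunctions:
    def test_fraction_half_at_centre(self):
        assert cline_fraction(40.0, 40.0, 15.0) == pytest.approx(0.5)

    def test_fraction_limits(self):
        assert cline_fraction(-1e6, 40.0, 15.0) == pytest.approx(0.0, abs=1e-12)
        assert cline_fraction(1e6, 40.0, 15.0) == pytest.approx(1.0, abs=1e-12)

    def test_fraction_closed_form(self):
        # 4 (47.5 - 40) / 15 = 2 -> 1 / (1 + e^-2)
        expected = 1.0 / (1.0 + np.exp(-2.0))
        assert cline_fraction(47.5, 40.0, 15.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.88080, abs=5e-6)

    def test_fraction_strictly_increasing(self):
        x = np.linspace(0, 76, 300)
        assert np.all(np.diff(cline_fraction(x, 40.0, 15.0)) > 0)

    def test_width_must_be_positive(self):
        with pytest.raises(ValueError):
            cline_fraction(1.0, 40.0, 0.0)

    def test_mean_at_centre_and_closed_form(self):
        assert cline_mean(40.0, PARAMS) == pytest.approx(2.0)
        f = 1.0 / (1.0 + np.exp(-2.0))
        assert cline_mean(47.5, PARAMS) == pytest.approx(1.0 + 2.0 * f, abs=1e-12)

    def test_mean_constant_when_ecotypes_equal(self):
        p = ClineParams(40, 15, 2.0, 2.0, 0.3, 0.3, 0.0)
        x = np.linspace(0, 76, 50)
        np.testing.assert_allclose(cline_mean(x, p), 2.0)

    def test_sd_at_centre(self):
        # f = 0.5 and 4f(1-f) = 1
        assert cline_sd(40.0, PARAMS) == pytest.approx((0.3 + 0.3) / 2 + 0.2)

    def test_sd_tail_limit_and_homoscedastic_case(self):
        assert cline_sd(-1e6, PARAMS) == pytest.approx(0.3, abs=1e-9)
        p = ClineParams(40, 15, 1, 3, 0.5, 0.5, 0.0)
        np.testing.assert_allclose(cline_sd(np.linspace(0, 76, 20), p), 0.5)

    def test_piecewise_sd_zones(self):
        p = ClineParams(40, 15, 1, 3, 0.3, 0.5, 0.4)
        sd = cline_sd(np.array([10.0, 40.0, 70.0]), p, sd_model="piecewise")
        np.testing.assert_allclose(sd, [0.3, 0.4, 0.5])


class TestNegLogLikelihood:
    def test_single_datum_at_mode(self):
        p = ClineParams(40, 15, 2, 2, 0.7, 0.7, 0.0)
        nll = neg_log_likelihood([40.0], [2.0], p)
        assert nll == pytest.approx(np.log(0.7 * np.sqrt(2 * np.pi)), abs=1e-12)

    def test_matches_naive_summation(self, rng):
        x = rng.uniform(0, 76, 40)
        y = rng.normal(2.0, 0.5, 40)
        naive = 0.0
        for xi, yi in zip(x, y):
            mu, sd = cline_mean(xi, PARAMS), cline_sd(xi, PARAMS)
            naive += np.log(sd) + 0.5 * np.log(2 * np.pi) + (yi - mu) ** 2 / (2 * sd**2)
        assert neg_log_likelihood(x, y, PARAMS) == pytest.approx(naive, abs=1e-10)

    def test_vanishing_sd_blows_up(self):
        p = ClineParams(40, 15, 2, 2, 1e-200, 1e-200, 0.0)
        assert neg_log_likelihood([40.0], [5.0], p) > 1e100

    def test_non_finite_data_rejected(self):
        with pytest.raises(ValueError):
            neg_log_likelihood([np.nan], [1.0], PARAMS)


class TestFitNull:
    def test_two_point_mle(self):
        null = fit_null([0.0, 1.0], [1.0, 3.0])
        assert null.mean == pytest.approx(2.0)
        assert null.sd == pytest.approx(1.0)  # ML divisor n

    def test_matches_closed_form_gaussian_likelihood(self, rng):
        y = rng.normal(5, 2, 200)
        x = rng.uniform(0, 76, 200)
        null = fit_null(x, y)
        sd = np.std(y)
        lnl = np.sum(-np.log(sd) - 0.5 * np.log(2 * np.pi)
                     - (y - y.mean()) ** 2 / (2 * sd**2))
        assert null.log_likelihood == pytest.approx(lnl, abs=1e-10)

    def test_nesting_identity_with_flat_cline(self, rng):
        """The null lnL equals the cline NLL at a flat parameterisation."""
        x = rng.uniform(0, 76, 50)
        y = rng.normal(0, 1, 50)
        null = fit_null(x, y)
        flat = ClineParams(40, 15, null.mean, null.mean, null.sd, null.sd, 0.0)
        assert -neg_log_likelihood(x, y, flat) == pytest.approx(null.log_likelihood,
                                                                abs=1e-10)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            fit_null([0, 1, 2], [1.0, 1.0, 1.0])


class TestFitCline:
    def test_parameter_recovery(self, rng):
        x = rng.uniform(0, 76, 200)
        y = rng.normal(cline_mean(x, PARAMS), cline_sd(x, PARAMS))
        fit = fit_cline(x, y, n_starts=8, seed=0)
        assert fit.converged
        assert fit.params.centre == pytest.approx(40.0, abs=2.0)
        assert fit.params.mu_crab == pytest.approx(1.0, abs=0.1)
        assert fit.params.mu_wave == pytest.approx(3.0, abs=0.1)

    def test_refit_from_optimum_is_stable(self, rng):
        x = rng.uniform(0, 76, 120)
        y = rng.normal(cline_mean(x, PARAMS), cline_sd(x, PARAMS))
        fit = fit_cline(x, y, n_starts=6, seed=0)
        refit = fit_cline(x, y, init=fit.params, n_starts=1, seed=1)
        assert refit.log_likelihood == pytest.approx(fit.log_likelihood, abs=1e-5)

    def test_constant_data_flagged_not_crashed(self):
        x = np.linspace(0, 76, 30)
        fit = fit_cline(x, np.full(30, 2.0), n_starts=2, seed=0)
        assert not fit.identifiable

    def test_nesting_inequality(self, rng):
        """Maximised cline lnL is never below the null lnL."""
        for i in range(5):
            r = np.random.default_rng(i)
            x = r.uniform(0, 76, 60)
            y = r.normal(0, 1, 60)
            fit = fit_cline(x, y, n_starts=2, seed=i)
            null = fit_null(x, y)
            assert fit.log_likelihood >= null.log_likelihood - 1e-6

    def test_position_shift_equivariance(self, rng):
        x = rng.uniform(0, 76, 150)
        y = rng.normal(cline_mean(x, PARAMS), cline_sd(x, PARAMS))
        fit0 = fit_cline(x, y, n_starts=6, seed=3)
        fit1 = fit_cline(x + 100.0, y, n_starts=6, seed=3)
        assert fit1.params.centre - fit0.params.centre == pytest.approx(100.0, abs=0.5)
        assert fit1.params.mu_crab == pytest.approx(fit0.params.mu_crab, abs=0.02)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_cline([1, 2, 3], [1, 2, 3], n_starts=1)


class TestLRT:
    def test_equal_likelihoods(self, rng):
        x = rng.uniform(0, 76, 30)
        y = rng.normal(0, 1, 30)
        null = fit_null(x, y)
        fit = fit_cline(x, y, n_starts=2, seed=0)
        lrt = likelihood_ratio_test(fit, null)
        assert lrt.chi2 >= 0.0
        assert 0.0 <= lrt.p_value <= 1.0

    def test_chi2_quantile_closed_form(self):
        from scipy import stats

        class FakeFit:
            log_likelihood = 11.0705 / 2

        class FakeNull:
            log_likelihood = 0.0

        lrt = likelihood_ratio_test(FakeFit(), FakeNull())
        assert lrt.df == 5
        assert lrt.p_value == pytest.approx(0.05, abs=1e-4)
        assert lrt.p_value == pytest.approx(stats.chi2.sf(11.0705, 5), abs=1e-12)

    def test_identical_likelihoods_give_p_one(self):
        class F:
            log_likelihood = -12.3

        lrt = likelihood_ratio_test(F(), F())
        assert lrt.chi2 == 0.0
        assert lrt.p_value == 1.0

    def test_large_negative_chi2_errors(self):
        class F:
            log_likelihood = 0.0

        class N:
            log_likelihood = 1.0

        with pytest.raises(ValueError):
            likelihood_ratio_test(F(), N())


class TestResiduals:
    def test_observation_at_fitted_mean_is_zero(self, rng):
        x = rng.uniform(0, 76, 50)
        y = rng.normal(cline_mean(x, PARAMS), cline_sd(x, PARAMS))
        fit = fit_cline(x, y, n_starts=4, seed=0)
        x0 = np.array([30.0])
        y0 = cline_mean(x0, fit.params)
        assert residuals(fit, x0, y0)[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_elementwise_subtraction(self, rng):
        x = rng.uniform(0, 76, 80)
        y = rng.normal(cline_mean(x, PARAMS), cline_sd(x, PARAMS))
        fit = fit_cline(x, y, n_starts=4, seed=0)
        oracle = np.array([yi - cline_mean(xi, fit.params) for xi, yi in zip(x, y)])
        np.testing.assert_array_equal(residuals(fit, x, y), oracle)
        np.testing.assert_array_equal(fit.residuals, oracle)

    def test_translation_equivariance(self, rng):
        """Residuals of shifted data under a mean-shifted fit are unchanged."""
        x = rng.uniform(0, 76, 40)
        y = rng.normal(cline_mean(x, PARAMS), cline_sd(x, PARAMS))
        fit = fit_cline(x, y, n_starts=4, seed=0)
        k = 7.5
        from dataclasses import replace
        shifted = replace(fit.params, mu_crab=fit.params.mu_crab + k,
                          mu_wave=fit.params.mu_wave + k)

        class ShiftedFit:
            params = shifted

        np.testing.assert_allclose(residuals(ShiftedFit(), x, y + k),
                                   residuals(fit, x, y), atol=1e-10)
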
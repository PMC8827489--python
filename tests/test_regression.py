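import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from mowg import (
    CensoredObservation,
    ParameterError,
    RegressionParams,
    censored_loglik,
    fit_regression,
    make_model,
    simulate_censored_cohort,
)
from mowg.regression import (
    _as_arrays,
    censored_loglik_expanded,
    fit_log_weibull,
    lmoww_logpdf,
    lmoww_logsf,
    lmoww_rvs,
)

TRUTH = RegressionParams(2.0, 1.5, 1.0, 0.8, (3.5, 0.6))


@pytest.fixture(scope="module")
def cohort():
    return simulate_censored_cohort(800, TRUTH, censoring_rate=0.2, seed=11)


class TestDensity:
    def test_change_of_variables_identity(self):
        # X with Weibull-baseline composition, shape 1/sigma, scale e^mu
        # implies log X has this log-location-scale density
        mu, sigma = 0.4, 0.8
        params = RegressionParams(2.0, 1.5, 1.0, sigma, (mu,))
        d = make_model("mow-w", [2.0, 1.5, 1.0, 1 / sigma, math.exp(mu)])
        ys = np.array([-1.2, -0.3, 0.2, 0.9, 1.7])
        lhs = lmoww_logpdf(ys, mu, params)
        rhs = d.logpdf(np.exp(ys)) + ys
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)

    def test_normalization(self):
        params = RegressionParams(2.0, 1.5, 1.0, 0.8, (0.0,))
        val, _ = integrate.quad(
            lambda y: math.exp(lmoww_logpdf(y, 0.0, params)), -30, 30,
            limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_log_weibull_reduction(self):
        # alpha = c = beta = 1: smallest-extreme-value density
        params = RegressionParams(1.0, 1.0, 1.0, 0.7, (0.3,))
        ys = np.linspace(-2, 2, 9)
        z = (ys - 0.3) / 0.7
        expect = -math.log(0.7) + z - np.exp(z)
        np.testing.assert_allclose(lmoww_logpdf(ys, 0.3, params), expect,
                                   rtol=1e-12)


class TestSurvival:
    def test_limit_at_minus_infinity(self):
        params = RegressionParams(3.0, 1.2, 0.9, 1.1, (0.0,))
        assert math.exp(lmoww_logsf(-40.0, 0.0, params)) == pytest.approx(1.0)

    def test_reduction_value(self):
        params = RegressionParams(1.0, 1.0, 1.0, 1.0, (0.0,))
        assert math.exp(lmoww_logsf(0.0, 0.0, params)) == pytest.approx(
            math.exp(-1.0))

    def test_one_minus_integral_of_density(self):
        params = RegressionParams(2.0, 1.5, 1.0, 0.8, (0.0,))
        for y in (-0.5, 0.3, 1.0):
            mass, _ = integrate.quad(
                lambda u: math.exp(lmoww_logpdf(u, 0.0, params)), -30, y,
                limit=200)
            assert math.exp(lmoww_logsf(y, 0.0, params)) == pytest.approx(
                1.0 - mass, abs=1e-8)


class TestCensoredLoglik:
    def test_hand_two_observation_case(self):
        params = RegressionParams(1.0, 1.0, 1.0, 1.0, (0.0,))
        data = [CensoredObservation(0.0, 1, (1.0,)),
                CensoredObservation(0.0, 0, (1.0,))]
        assert censored_loglik(data, params) == pytest.approx(-2.0)

    def test_all_events_equals_density_sum(self, cohort):
        events = [o for o in cohort if o.event == 1]
        y, _, V = _as_arrays(events)
        mu = V @ np.asarray(TRUTH.tau)
        assert censored_loglik(events, TRUTH) == pytest.approx(
            float(np.sum(lmoww_logpdf(y, mu, TRUTH))), rel=1e-12)

    def test_all_censored_equals_survival_sum(self, cohort):
        cens = [o for o in cohort if o.event == 0]
        y, _, V = _as_arrays(cens)
        mu = V @ np.asarray(TRUTH.tau)
        assert censored_loglik(cens, TRUTH) == pytest.approx(
            float(np.sum(lmoww_logsf(y, mu, TRUTH))), rel=1e-12)

    def test_compact_equals_expanded(self, cohort):
        rng = np.random.default_rng(8)
        for _ in range(5):
            pr = RegressionParams(
                float(np.exp(rng.uniform(-1.5, 1.5))),
                float(np.exp(rng.uniform(-0.7, 0.7))),
                float(np.exp(rng.uniform(-0.7, 0.7))),
                float(np.exp(rng.uniform(-0.7, 0.7))),
                (float(rng.normal(3.5, 1)), float(rng.normal(0.6, 0.5))),
            )
            assert censored_loglik(cohort, pr) == pytest.approx(
                censored_loglik_expanded(cohort, pr), abs=1e-10)

    def test_rank_deficiency_rejected(self):
        data = [CensoredObservation(0.1 * i, 1, (1.0, 2.0)) for i in range(10)]
        with pytest.raises(ParameterError, match="rank"):
            censored_loglik(data, RegressionParams(1, 1, 1, 1, (0.0, 0.0)))


class TestObservationValidation:
    def test_bad_event(self):
        with pytest.raises(ParameterError):
            CensoredObservation(0.0, 2, (1.0,))

    def test_missing_intercept(self):
        with pytest.raises(ParameterError):
            CensoredObservation(0.0, 1, (0.5,))


class TestCohortGenerator:
    def test_censoring_calibration(self):
        coh = simulate_censored_cohort(5000, TRUTH, censoring_rate=0.2,
                                       seed=21)
        frac = np.mean([1 - o.event for o in coh])
        assert abs(frac - 0.2) < 0.03

    def test_zero_rate_all_events(self):
        coh = simulate_censored_cohort(200, TRUTH, censoring_rate=0.0, seed=1)
        assert all(o.event == 1 for o in coh)

    def test_deterministic(self):
        a = simulate_censored_cohort(100, TRUTH, censoring_rate=0.3, seed=5)
        b = simulate_censored_cohort(100, TRUTH, censoring_rate=0.3, seed=5)
        assert all(x.y == y.y and x.event == y.event for x, y in zip(a, b))

    def test_survival_distribution_of_lifetimes(self):
        # uncensored generation times match the model survival function
        params = RegressionParams(2.0, 1.5, 1.0, 0.8, (0.5,))
        y = lmoww_rvs(20000, 0.5, params, seed=13)
        for yq in (-0.5, 0.3, 1.0):
            emp = np.mean(y > yq)
            model = math.exp(lmoww_logsf(yq, 0.5, params))
            assert emp == pytest.approx(model, abs=0.015)

    def test_invalid_rate(self):
        with pytest.raises(ParameterError):
            simulate_censored_cohort(10, TRUTH, censoring_rate=1.0, seed=0)


class TestFitRegression:
    def test_zero_events_rejected(self):
        data = [CensoredObservation(0.1 * i, 0, (1.0, i % 2))
                for i in range(20)]
        with pytest.raises(ParameterError, match="events"):
            fit_regression(data)

    def test_recovery_of_identifiable_parameters(self, cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_regression(cohort, seed=3)
        assert fit.converged
        p = fit.params
        # the likelihood depends on (c, beta, sigma, tau0) only through
        # a = c/sigma and b = tau0 + sigma log(beta): check those
        a_true = TRUTH.c / TRUTH.sigma
        b_true = TRUTH.tau[0] + TRUTH.sigma * math.log(TRUTH.beta)
        assert p.c / p.sigma == pytest.approx(a_true, rel=0.25)
        assert p.tau[0] + p.sigma * math.log(p.beta) == pytest.approx(
            b_true, abs=0.25)
        # slope is identifiable and must be within 3 SE
        se_tau1 = fit.se[5]
        assert abs(p.tau[1] - TRUTH.tau[1]) < 3 * se_tau1

    def test_aic_bic_arithmetic(self, cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_regression(cohort, seed=3, compute_se=False)
        k = fit.params.k
        assert fit.aic == pytest.approx(2 * k + 2 * fit.negloglik)
        assert fit.bic == pytest.approx(k * math.log(fit.n) + 2 * fit.negloglik)
        assert fit.r == sum(o.event for o in cohort)

    def test_log_weibull_anchor_matches_lifelines(self, cohort):
        lifelines = pytest.importorskip("lifelines")
        y, e, V = _as_arrays(cohort)
        sigma, tau, nll = fit_log_weibull(y, e, V)
        df = pd.DataFrame({"T": np.exp(y), "E": e, "arm": V[:, 1]})
        aft = lifelines.WeibullAFTFitter().fit(df, "T", "E")
        # lifelines works on the natural-time scale: the Jacobian of the
        # log transform shifts the likelihood by the sum of event log-times
        nll_natural = -float(aft.log_likelihood_)
        assert nll == pytest.approx(nll_natural - y[e == 1].sum(), abs=1e-3)
        sigma_ll = float(np.exp(-aft.summary.loc[("rho_", "Intercept"),
                                                 "coef"]))
        assert sigma == pytest.approx(sigma_ll, rel=1e-3)
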
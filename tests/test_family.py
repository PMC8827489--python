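import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from mowg import (
    GeneratorParams,
    MOWGDistribution,
    ParameterError,
    exponential_baseline,
    mo_cdf,
    mowg_cdf,
    mowg_hazard,
    mowg_median,
    mowg_pdf,
    mowg_quantile,
    mowg_rvs,
    weibull_baseline,
    weibullg_cdf,
)

positive = st.floats(min_value=0.05, max_value=5.0)


class TestGeneratorParams:
    def test_rejects_nonpositive(self):
        for bad in [dict(alpha=0.0, c=1, beta=1), dict(alpha=1, c=-2, beta=1),
                    dict(alpha=1, c=1, beta=float("nan"))]:
            with pytest.raises(ParameterError):
                GeneratorParams(**bad)

    def test_alpha_bar_derived(self):
        assert GeneratorParams(0.3, 1, 1).alpha_bar == pytest.approx(0.7)


class TestTiltTransform:
    def test_identity_at_one(self):
        assert mo_cdf(1.0, 0.3) == pytest.approx(0.3)

    def test_boundary_preservation(self):
        for a in (0.2, 1.0, 7.0):
            assert mo_cdf(a, 0.0) == 0.0
            assert mo_cdf(a, 1.0) == 1.0

    def test_direct_arithmetic(self):
        assert mo_cdf(2.0, 0.5) == pytest.approx(0.5 / (2.0 - 0.5))

    def test_rejects_bad_alpha(self):
        with pytest.raises(ParameterError):
            mo_cdf(0.0, 0.5)

    def test_rejects_out_of_range_cdf(self):
        with pytest.raises(ParameterError):
            mo_cdf(1.0, 1.5)


class TestWeibullTransform:
    def test_unit_case(self):
        g = 1.0 - math.exp(-1.0)
        assert weibullg_cdf(1.0, 1.0, g) == pytest.approx(g, abs=1e-12)

    def test_zero_maps_to_zero(self):
        assert weibullg_cdf(2.3, 0.7, 0.0) == 0.0

    def test_inner_unit(self):
        g = 1.0 - math.exp(-2.0)
        assert weibullg_cdf(2.0, 2.0, g) == pytest.approx(1.0 - math.exp(-1.0))

    def test_one_maps_to_one(self):
        assert weibullg_cdf(2.0, 2.0, 1.0) == 1.0

    @given(c=positive, beta=positive,
           g=st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_strictly_increasing(self, c, beta, g):
        assert weibullg_cdf(c, beta, g + 5e-7) >= weibullg_cdf(c, beta, g)


class TestCdf:
    def test_reduces_to_exponential_median(self, plain_exp):
        assert mowg_cdf(plain_exp, math.log(2.0)) == pytest.approx(0.5)

    def test_tilted_value(self, tilted_exp):
        expect = (1 - math.exp(-1)) / (1 + math.exp(-1))
        assert mowg_cdf(tilted_exp, 1.0) == pytest.approx(expect, abs=1e-10)

    def test_zero_below_support(self, sweep):
        for d in sweep:
            assert mowg_cdf(d, 0.0) == 0.0
            assert mowg_cdf(d, -3.0) == 0.0

    def test_composition_identity(self, sweep):
        xs = np.linspace(0.05, 6.0, 40)
        for d in sweep:
            direct = mowg_cdf(d, xs)
            composed = mo_cdf(
                d.gen.alpha,
                weibullg_cdf(d.gen.c, d.gen.beta, d.baseline.cdf(xs)),
            )
            np.testing.assert_allclose(direct, composed, atol=1e-12)

    def test_nondecreasing(self, sweep):
        xs = np.linspace(0.0, 12.0, 300)
        for d in sweep:
            assert np.all(np.diff(mowg_cdf(d, xs)) >= -1e-14)


class TestPdf:
    def test_reduction_limit_at_origin(self, plain_exp):
        assert mowg_pdf(plain_exp, 1e-12) == pytest.approx(1.0, rel=1e-6)

    def test_normalization_quadrature(self):
        d = MOWGDistribution(GeneratorParams(0.5, 2.0, 1.0),
                             exponential_baseline(1.0))
        val, _ = integrate.quad(lambda x: mowg_pdf(d, x), 0, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_matches_cdf_derivative(self, sweep):
        h = 1e-5
        for d in sweep:
            x = 0.7
            fd = (mowg_cdf(d, x + h) - mowg_cdf(d, x - h)) / (2 * h)
            assert mowg_pdf(d, x) == pytest.approx(fd, rel=1e-4)

    def test_logpdf_consistent(self, sweep):
        xs = np.array([0.3, 1.1, 2.5])
        for d in sweep:
            np.testing.assert_allclose(np.exp(d.logpdf(xs)), d.pdf(xs),
                                       rtol=1e-12)

    def test_zero_outside_support(self, sweep):
        for d in sweep:
            assert mowg_pdf(d, -1.0) == 0.0


class TestQuantile:
    def test_p_zero_is_support_infimum(self, sweep):
        for d in sweep:
            assert mowg_quantile(d, 0.0) == 0.0

    def test_hand_inversion(self, tilted_exp):
        # (1-p)/(1-(1-2)p) at p=0.5 gives 1/3, so x = -log(1/3)
        q = mowg_quantile(tilted_exp, 0.5)
        assert q == pytest.approx(math.log(3.0), abs=1e-10)
        assert mowg_cdf(tilted_exp, q) == pytest.approx(0.5, abs=1e-10)

    def test_round_trip(self, sweep):
        ps = np.linspace(0.01, 0.99, 50)
        for d in sweep:
            np.testing.assert_allclose(mowg_cdf(d, mowg_quantile(d, ps)), ps,
                                       atol=1e-8)

    def test_domain_error(self, plain_exp):
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ParameterError):
                mowg_quantile(plain_exp, bad)


class TestMedian:
    def test_exponential_reduction(self, plain_exp):
        assert mowg_median(plain_exp) == pytest.approx(math.log(2.0))

    def test_tilted_value(self, tilted_exp):
        assert mowg_median(tilted_exp) == pytest.approx(1.0986, abs=1e-4)

    def test_median_is_half_quantile(self, sweep):
        for d in sweep:
            assert mowg_cdf(d, mowg_median(d)) == pytest.approx(0.5, abs=1e-10)


class TestHazard:
    def test_hazard_survival_density_identity(self, sweep):
        xs = np.array([0.4, 1.3, 2.2])
        for d in sweep:
            np.testing.assert_allclose(
                mowg_hazard(d, xs) * d.sf(xs), d.pdf(xs), rtol=1e-10)

    def test_constant_for_exponential_reduction(self):
        d = MOWGDistribution(GeneratorParams(1.0, 1.0, 2.0),
                             exponential_baseline(3.0))
        xs = np.linspace(0.1, 5.0, 20)
        np.testing.assert_allclose(mowg_hazard(d, xs), 1.5, rtol=1e-10)

    def test_nonnegative(self, sweep):
        xs = np.linspace(0.05, 8.0, 30)
        for d in sweep:
            assert np.all(mowg_hazard(d, xs) >= 0.0)


class TestRvs:
    def test_seed_determinism(self, plain_exp):
        a = mowg_rvs(plain_exp, 100, seed=7)
        b = mowg_rvs(plain_exp, 100, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_exponential_mean(self, plain_exp):
        n = 100_000
        x = mowg_rvs(plain_exp, n, seed=1)
        assert abs(x.mean() - 1.0) < 3.0 / math.sqrt(n)

    def test_ks_against_cdf(self):
        d = MOWGDistribution(GeneratorParams(0.4, 1.8, 0.9),
                             weibull_baseline(1.3, 1.1))
        x = mowg_rvs(d, 4000, seed=3)
        p = stats.kstest(x, lambda v: mowg_cdf(d, v)).pvalue
        assert p > 0.01

    def test_rejects_bad_n(self, plain_exp):
        with pytest.raises(ParameterError):
            mowg_rvs(plain_exp, 0, seed=1)


class TestReductions:
    def test_alpha_one_is_untilted(self, exp1):
        d = MOWGDistribution(GeneratorParams(1.0, 1.7, 0.8), exp1)
        xs = np.linspace(0.1, 4.0, 25)
        np.testing.assert_allclose(
            d.cdf(xs), weibullg_cdf(1.7, 0.8, exp1.cdf(xs)), atol=1e-14)

    def test_full_reduction_to_exponential(self):
        lam = 2.3
        d = MOWGDistribution(GeneratorParams(1.0, 1.0, 1.0),
                             exponential_baseline(lam))
        xs = np.linspace(0.1, 3.0, 25)
        np.testing.assert_allclose(d.cdf(xs), 1 - np.exp(-lam * xs),
                                   atol=1e-14)


@settings(max_examples=40, deadline=None)
@given(alpha=positive, c=positive, beta=positive,
       p=st.floats(min_value=1e-4, max_value=1 - 1e-4))
def test_property_round_trip(alpha, c, beta, p):
    d = MOWGDistribution(GeneratorParams(alpha, c, beta),
                         exponential_baseline(1.0))
    assert mowg_cdf(d, mowg_quantile(d, p)) == pytest.approx(p, abs=1e-8)


@pytest.mark.parametrize("alpha,c,beta", [
    (0.05, 0.7, 1.3), (0.5, 2.0, 1.0), (2.5, 1.4, 0.6), (5.0, 0.5, 2.0),
])
@pytest.mark.parametrize("baseline", ["exponential", "weibull"])
def test_property_normalization(alpha, c, beta, baseline):
    base = (exponential_baseline(0.8) if baseline == "exponential"
            else weibull_baseline(1.7, 1.2))
    d = MOWGDistribution(GeneratorParams(alpha, c, beta), base)
    # integrate in the quantile domain to avoid tail truncation
    val, _ = integrate.quad(lambda x: d.pdf(x), 0, np.inf, limit=200)
    assert val == pytest.approx(1.0, abs=1e-6)


def test_weibull_baseline_density_limit_at_origin():
    # shape < 1: the density diverges at 0+; the limit value is returned
    d = MOWGDistribution(GeneratorParams(1.0, 1.0, 1.0),
                         weibull_baseline(0.5, 1.0))
    assert mowg_pdf(d, 1e-300) > 1e100
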
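"""Moments, entropies, PWMs, order statistics and quantile shape measures:
closed-form special cases, quadrature-vs-series cross-checks, and
Monte Carlo oracles."""

import numpy as np
import pytest
from scipy import integrate, optimize

from lomaxg import NLWParams, nlw, properties
from lomaxg.properties import (EntropySpec, MgfDomainError, MomentSpec,
                               SeriesConvergenceError, cf, mean_variance, mgf,
                               order_stat_pdf, pwm, quantile_kurtosis,
                               quantile_skewness, raw_moment, renyi_entropy,
                               shannon_entropy)

EXP_CASE = NLWParams(alpha=1.6, beta=1.0, lam=0.4, theta=1.0, c=1.0)
SET_I = NLWParams(alpha=1.65, beta=1.98, lam=0.055, theta=0.59, c=2.5)
# integer shape k = c*beta = 2 makes the binomial series finite, hence exact
SERIES_CASE = NLWParams(alpha=1.2, beta=1.0, lam=0.5, theta=1.3, c=2.0)


class TestRawMoments:
    def test_shifted_exponential_mean(self):
        assert raw_moment(EXP_CASE, 1) == pytest.approx(1 / 1.6 - 0.4, rel=1e-9)

    def test_rayleigh_mean(self):
        p = NLWParams(alpha=0.5, beta=2.0, lam=0.0, theta=1.7, c=1.0)
        assert raw_moment(p, 1) == pytest.approx(1.7 * np.sqrt(np.pi / 2),
                                                 rel=1e-9)

    def test_series_agrees_with_quadrature(self):
        for r in (1, 2, 3):
            quad = raw_moment(SERIES_CASE, r)
            ser = raw_moment(SERIES_CASE, MomentSpec(r, method="series"))
            assert ser == pytest.approx(quad, rel=1e-4), r

    def test_series_signals_nonconvergence(self):
        neg_lam = NLWParams(alpha=1.0, beta=1.0, lam=-0.5, theta=1.0, c=2.0)
        with pytest.raises(SeriesConvergenceError):
            raw_moment(neg_lam, MomentSpec(1, method="series"))


class TestMeanVariance:
    def test_exponential_variance(self):
        _, var = mean_variance(EXP_CASE)
        assert var == pytest.approx(1 / 1.6 ** 2, rel=1e-8)

    def test_variance_invariant_to_location(self):
        p = NLWParams(alpha=0.9, beta=1.4, lam=0.2, theta=1.1, c=1.6)
        q = NLWParams(alpha=0.9, beta=1.4, lam=-1.8, theta=1.1, c=1.6)
        assert mean_variance(p)[1] == pytest.approx(mean_variance(q)[1],
                                                    rel=1e-8)
        assert mean_variance(q)[0] - mean_variance(p)[0] == pytest.approx(
            2.0, rel=1e-8)

    def test_against_monte_carlo(self, set2_params):
        mu, var = mean_variance(set2_params)
        x = nlw.rvs(set2_params, 10 ** 6, seed=5)
        se_mu = np.sqrt(var / x.size)
        assert abs(x.mean() - mu) < 3 * se_mu
        m4 = np.mean((x - mu) ** 4)
        se_var = np.sqrt(max(m4 - var ** 2, 0.0) / x.size)
        assert abs(x.var() - var) < 3 * se_var


class TestGeneratingFunctions:
    def test_normalization_at_zero(self, set2_params):
        assert mgf(set2_params, 0.0) == pytest.approx(1.0, rel=1e-10)
        assert cf(set2_params, 0.0) == pytest.approx(1.0 + 0j, rel=1e-10)

    def test_mgf_derivative_is_mean(self, set2_params):
        h = 1e-5
        fd = (mgf(set2_params, h) - mgf(set2_params, -h)) / (2 * h)
        assert fd == pytest.approx(mean_variance(set2_params)[0], rel=1e-6)

    def test_shifted_exponential_mgf(self):
        p = EXP_CASE
        for t in (-1.0, 0.5, 1.2):
            assert mgf(p, t) == pytest.approx(
                np.exp(-t * p.lam) * p.alpha / (p.alpha - t), rel=1e-8)

    def test_divergence_signalled(self):
        heavy = NLWParams(alpha=1, beta=0.5, lam=0, theta=1, c=1)  # k < 1
        with pytest.raises(MgfDomainError):
            mgf(heavy, 0.1)
        with pytest.raises(MgfDomainError):
            mgf(EXP_CASE, EXP_CASE.alpha)  # at/above the exponential rate
        assert np.isfinite(mgf(heavy, -0.5))  # t <= 0 always fine

    def test_cf_matches_mc(self, set2_params):
        x = nlw.rvs(set2_params, 10 ** 5, seed=9)
        val = cf(set2_params, 0.7)
        emp = np.exp(1j * 0.7 * x).mean()
        assert abs(val - emp) < 5e-3


class TestPWM:
    def test_s_zero_reduces_to_raw_moment(self, set2_params):
        assert pwm(set2_params, MomentSpec(2, 0)) == pytest.approx(
            raw_moment(set2_params, 2), rel=1e-9)

    def test_r_zero_probability_integral_transform(self, set2_params):
        for s in (1, 2, 5):
            assert pwm(set2_params, MomentSpec(0, s)) == pytest.approx(
                1.0 / (s + 1), rel=1e-8)

    def test_series_agrees_with_quadrature(self):
        spec_q = MomentSpec(1, 2)
        spec_s = MomentSpec(1, 2, method="series")
        assert pwm(SERIES_CASE, spec_s) == pytest.approx(
            pwm(SERIES_CASE, spec_q), rel=1e-3)


class TestOrderStatistics:
    def test_single_observation_is_parent_density(self, set2_params):
        x = np.linspace(0.0, 6.0, 50)
        np.testing.assert_allclose(order_stat_pdf(set2_params, 1, 1, x),
                                   nlw.pdf(set2_params, x), rtol=1e-12)

    def test_maximum_closed_form(self, set2_params):
        x = np.linspace(0.0, 6.0, 50)
        n = 4
        expect = n * nlw.cdf(set2_params, x) ** (n - 1) * nlw.pdf(set2_params, x)
        np.testing.assert_allclose(order_stat_pdf(set2_params, n, n, x),
                                   expect, rtol=1e-12)

    def test_integrates_to_one_over_full_sweep(self, set2_params):
        p = set2_params
        for n in range(1, 7):
            for r in range(1, n + 1):
                val, _ = integrate.quad(
                    lambda x: order_stat_pdf(p, r, n, x), -p.lam, np.inf,
                    limit=200)
                assert val == pytest.approx(1.0, rel=1e-6), (r, n)

    def test_invalid_rank_rejected(self, set2_params):
        with pytest.raises(ValueError):
            order_stat_pdf(set2_params, 0, 3, 1.0)
        with pytest.raises(ValueError):
            order_stat_pdf(set2_params, 4, 3, 1.0)


class TestEntropies:
    def test_renyi_closed_form_vs_quadrature(self):
        assert renyi_entropy(SET_I, 2.0) == pytest.approx(
            renyi_entropy(SET_I, 2.0, method="quadrature"), rel=1e-6)

    def test_renyi_location_invariance(self):
        p = NLWParams(alpha=1.2, beta=1.5, lam=0.3, theta=0.8, c=1.1)
        q = NLWParams(alpha=1.2, beta=1.5, lam=-2.0, theta=0.8, c=1.1)
        assert renyi_entropy(p, 0.5) == pytest.approx(renyi_entropy(q, 0.5),
                                                      rel=1e-12)

    def test_renyi_limit_approaches_shannon(self, set2_params):
        assert renyi_entropy(set2_params, 1.001) == pytest.approx(
            shannon_entropy(set2_params), abs=1e-2)

    def test_renyi_divergence_signalled(self):
        # k_const <= 0: small u with k < 1 cannot happen (k_const > 0 for
        # u < 1); divergence needs u(1 - 1/k)... take k tiny, u large.
        p = NLWParams(alpha=1, beta=0.2, lam=0, theta=1, c=1)  # k = 0.2
        with pytest.raises(MgfDomainError):
            renyi_entropy(p, 2.0)  # k_const = (2*0.2 - 2 + 1)/0.2 = -3

    def test_shannon_exponential_closed_form(self):
        assert shannon_entropy(EXP_CASE) == pytest.approx(
            1 - np.log(EXP_CASE.alpha), rel=1e-8)

    def test_shannon_against_monte_carlo(self, set2_params):
        h = shannon_entropy(set2_params)
        x = nlw.rvs(set2_params, 10 ** 6, seed=17)
        lp = nlw.logpdf(set2_params, x)
        assert abs(-lp.mean() - h) < 3 * lp.std() / np.sqrt(x.size)


class TestQuantileShape:
    def test_recomputed_from_quantile_arithmetic(self, set2_params):
        p = set2_params
        q = {lv: nlw.quantile(p, lv) for lv in
             (0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875)}
        assert quantile_skewness(p) == pytest.approx(
            (q[0.75] - 2 * q[0.5] + q[0.25]) / (q[0.75] - q[0.5]), rel=1e-12)
        assert quantile_kurtosis(p, standard=True) == pytest.approx(
            (q[0.875] - q[0.625] + q[0.375] - q[0.125])
            / (q[0.75] - q[0.25]), rel=1e-12)

    def test_location_invariance(self, set2_params):
        p = set2_params
        shifted = NLWParams(alpha=p.alpha, beta=p.beta, lam=p.lam + 3.0,
                            theta=p.theta, c=p.c)
        for fn in (quantile_skewness, quantile_kurtosis):
            assert fn(p) == pytest.approx(fn(shifted), rel=1e-10)
            assert fn(p, standard=True) == pytest.approx(
                fn(shifted, standard=True), rel=1e-10)

    def test_symmetric_quantile_spacing_gives_zero_skewness(self):
        """Solve for the Weibull shape whose quartiles are equally spaced;
        there the quantile-skewness numerator vanishes by construction."""
        l4, l2, l43 = np.log(4), np.log(2), np.log(4 / 3)

        def spacing(k):
            return (l4 ** (1 / k) - 2 * l2 ** (1 / k) + l43 ** (1 / k))

        k_sym = optimize.brentq(spacing, 1.0, 10.0)
        p = NLWParams(alpha=1.0, beta=k_sym, lam=0.0, theta=1.0, c=1.0)
        assert abs(quantile_skewness(p)) < 1e-6
        assert abs(quantile_skewness(p, standard=True)) < 1e-6
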
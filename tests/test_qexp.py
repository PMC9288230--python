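"""Unit and property tests for the q-exponential distribution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from airtails.errors import ConvergenceError, DataError, ParameterError
from airtails.qexp import (QExpParams, qexp_cdf, qexp_loglik, qexp_mean,
                           qexp_mle, qexp_pdf, qexp_quantile, qexp_sample,
                           superstat_q)

PARAM_GRID = [QExpParams(q, lam)
              for q in (0.5, 0.8, 1.0, 1.2, 1.5, 1.9)
              for lam in (0.01, 1.0, 100.0)]


class TestParams:
    @pytest.mark.parametrize("q,lam", [(0.0, 1.0), (2.0, 1.0), (-0.5, 1.0),
                                       (1.0, 0.0), (1.0, -2.0)])
    def test_invalid_parameters_rejected(self, q, lam):
        with pytest.raises(ParameterError):
            QExpParams(q, lam)

    def test_finite_support_below_one(self):
        p = QExpParams(0.5, 1.0)
        assert p.support_upper == pytest.approx(2.0)
        assert QExpParams(1.5, 1.0).support_upper == np.inf

    def test_tail_exponent(self):
        assert QExpParams(1.5, 1.0).tail_exponent == pytest.approx(-2.0)
        with pytest.raises(ParameterError):
            QExpParams(0.9, 1.0).tail_exponent


class TestPdf:
    def test_density_at_origin_limit(self):
        # f(0+) = (2 - q) * lam
        assert qexp_pdf(QExpParams(1.0, 2.0), 1e-12) == pytest.approx(2.0, rel=1e-9)

    def test_exponential_special_case(self):
        assert qexp_pdf(QExpParams(1.0, 1.0), 1.0) == pytest.approx(np.exp(-1.0))

    def test_zero_outside_finite_support(self):
        # support of (q=0.5, lam=1) ends at 1/(lam*(1-q)) = 2
        assert qexp_pdf(QExpParams(0.5, 1.0), 2.5) == 0.0
        assert qexp_pdf(QExpParams(1.2, 1.0), -1.0) == 0.0
        assert qexp_pdf(QExpParams(1.2, 1.0), 0.0) == 0.0

    def test_power_law_tail_ratio(self):
        # for q = 1.5 the tail exponent is -1/(q-1) = -2, so f(2x)/f(x) -> 2^-2
        p = QExpParams(1.5, 1.0)
        for x in (1e3, 1e4):
            assert qexp_pdf(p, 2 * x) / qexp_pdf(p, x) == pytest.approx(0.25, rel=2e-3)

    @pytest.mark.parametrize("params", PARAM_GRID, ids=str)
    def test_normalizes_to_one(self, params):
        upper = min(params.support_upper, np.inf)
        total, _ = integrate.quad(lambda x: qexp_pdf(params, x), 0, upper, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("side", [1e-4, -1e-4])
    def test_continuity_at_exponential_limit(self, side):
        lam = 1.0
        x = np.linspace(1e-6, 20, 2000)
        f = qexp_pdf(QExpParams(1.0 + side, lam), x)
        assert np.max(np.abs(f - lam * np.exp(-lam * x))) < 1e-3

    def test_log_density_slope_matches_tail_exponent(self):
        # log f vs log x is asymptotically linear with slope -1/(q-1)
        p = QExpParams(1.4, 1.0)
        x = np.logspace(3, 6, 50)
        slope = np.polyfit(np.log(x), np.log(qexp_pdf(p, x)), 1)[0]
        assert slope == pytest.approx(-1.0 / 0.4, rel=1e-3)


class TestCdfQuantile:
    def test_exponential_cdf(self):
        assert qexp_cdf(QExpParams(1.0, 1.0), 1.0) == pytest.approx(1 - np.exp(-1))

    def test_total_mass_at_support_end(self):
        assert qexp_cdf(QExpParams(0.5, 1.0), 2.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("params", PARAM_GRID, ids=str)
    def test_cdf_matches_integrated_density(self, params):
        x = min(params.support_upper, 3.0 / params.lam) * 0.7
        expected, _ = integrate.quad(lambda t: qexp_pdf(params, t), 0, x, limit=200)
        assert qexp_cdf(params, x) == pytest.approx(expected, abs=1e-8)

    def test_quantile_at_zero(self):
        assert qexp_quantile(QExpParams(1.3, 2.0), 0.0) == 0.0

    def test_exponential_median(self):
        assert qexp_quantile(QExpParams(1.0, 2.0), 0.5) == pytest.approx(np.log(2) / 2)

    @pytest.mark.parametrize("params", PARAM_GRID, ids=str)
    def test_cdf_quantile_round_trip(self, params):
        p = np.linspace(0.0, 0.999, 101)
        assert np.allclose(qexp_cdf(params, qexp_quantile(params, p)), p, atol=1e-10)

    def test_quantile_domain_error(self):
        with pytest.raises(DataError):
            qexp_quantile(QExpParams(1.2, 1.0), 1.0)
        with pytest.raises(DataError):
            qexp_quantile(QExpParams(1.2, 1.0), -0.1)


class TestSampling:
    def test_reproducible_for_fixed_seed(self):
        p = QExpParams(1.2, 1.0)
        assert np.array_equal(qexp_sample(p, 1000, seed=7), qexp_sample(p, 1000, seed=7))

    def test_ks_against_closed_form_cdf(self):
        p = QExpParams(1.2, 1.0)
        x = qexp_sample(p, 10**5, seed=11)
        res = stats.kstest(x, lambda t: qexp_cdf(p, t))
        assert res.pvalue > 0.01

    def test_sample_mean_matches_formula(self):
        # mean = 1/(lam*(3-2q)) = 2.0 for q=1.25, lam=1
        p = QExpParams(1.25, 1.0)
        x = qexp_sample(p, 10**6, seed=13)
        se = np.std(x) / np.sqrt(x.size)
        assert abs(np.mean(x) - 2.0) < 3 * se


class TestLoglik:
    def test_single_exponential_point(self):
        assert qexp_loglik(QExpParams(1.0, 1.0), [2.5]) == pytest.approx(-2.5)

    def test_point_outside_support_gives_minus_inf(self):
        assert qexp_loglik(QExpParams(0.5, 1.0), [0.5, 3.0]) == -np.inf

    def test_matches_elementwise_log_pdf(self, rng):
        p = QExpParams(1.3, 0.5)
        x = qexp_sample(p, 500, rng=rng)
        expected = np.sum(np.log(qexp_pdf(p, x)))
        assert qexp_loglik(p, x) == pytest.approx(expected, abs=1e-12)

    def test_empty_data_error(self):
        with pytest.raises(DataError):
            qexp_loglik(QExpParams(1.0, 1.0), [])


class TestMle:
    def test_recovers_heavy_tail_parameters(self):
        true = QExpParams(1.3, 0.1)
        x = qexp_sample(true, 10**5, seed=3)
        est, ll = qexp_mle(x)
        assert abs(est.q - 1.3) < 0.02
        assert abs(est.lam - 0.1) / 0.1 < 0.05
        assert ll == pytest.approx(qexp_loglik(est, x))

    def test_exponential_data_gives_q_near_one(self, rng):
        x = rng.exponential(1.0, 10**5)
        est, _ = qexp_mle(x)
        assert abs(est.q - 1.0) < 0.02

    def test_finite_support_regime_reachable(self):
        true = QExpParams(0.8, 1.0)
        x = qexp_sample(true, 10**5, seed=5)
        est, _ = qexp_mle(x)
        assert abs(est.q - 0.8) < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            qexp_mle(np.ones(1000))
        with pytest.raises(DataError):
            qexp_mle(np.arange(1, 30, dtype=float))
        with pytest.raises(DataError):
            qexp_mle(np.linspace(-1, 5, 100))

    def test_bias_shrinks_with_sample_size(self):
        true = QExpParams(1.3, 1.0)
        med_err = []
        for n in (10**3, 10**4, 10**5):
            errs = [abs(qexp_mle(qexp_sample(true, n, seed=100 * n + k))[0].q - 1.3)
                    for k in range(5)]
            med_err.append(np.median(errs))
        assert med_err[0] >= med_err[1] >= med_err[2]


class TestMoments:
    def test_exponential_mean(self):
        assert qexp_mean(QExpParams(1.0, 2.0)) == pytest.approx(0.5)

    def test_mean_matches_quadrature(self):
        p = QExpParams(1.25, 1.0)
        expected, _ = integrate.quad(lambda x: x * qexp_pdf(p, x), 0, np.inf, limit=400)
        assert qexp_mean(p) == pytest.approx(expected, rel=1e-6)
        assert qexp_mean(p) == pytest.approx(2.0)

    def test_divergent_mean_raises(self):
        with pytest.raises(ParameterError):
            qexp_mean(QExpParams(1.5, 1.0))


class TestSuperstatQ:
    def test_constant_rate_gives_one(self):
        assert superstat_q([2.0, 2.0, 2.0]) == pytest.approx(1.0)

    def test_two_point_rate(self):
        assert superstat_q([1.0, 3.0]) == pytest.approx(1.25)

    def test_gamma_rate_moment_identity(self, rng):
        # <lam^2>/<lam>^2 = 1 + 1/a for a Gamma(a) rate
        a = 4.0
        lam = rng.gamma(a, 1.0, 10**6)
        q = superstat_q(lam)
        se = 3 * np.std(lam**2) / np.mean(lam) ** 2 / np.sqrt(lam.size)
        assert abs(q - 1.25) < se

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(DataError):
            superstat_q([1.0, 0.0])
        with pytest.raises(DataError):
            superstat_q([])

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 1e3), min_size=1, max_size=50))
    def test_always_at_least_one(self, lams):
        assert superstat_q(lams) >= 1.0 - 1e-12
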
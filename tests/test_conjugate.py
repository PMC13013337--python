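"""Conjugate families: matching inversions, updates, quadrature oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, special, stats

from carecast.conjugate import (
    BetaParams,
    GammaParams,
    MomentMatchingError,
    NIGParams,
    beta_from_logit_moments,
    gamma_from_log_moments,
    log_moments_from_gamma,
    logit_moments_from_beta,
    nig_from_predictor_moments,
    predictor_moments_from_nig,
    sample_ztp,
    update_bernoulli,
    update_gaussian,
    update_positive_count,
    ztp_mean,
    ztp_pmf,
)
from carecast.state import PredictorMoments

EULER = -special.digamma(1.0)  # 0.5772...


class TestBetaLogitMatching:
    def test_uniform_equivalent(self):
        b = beta_from_logit_moments(PredictorMoments(0.0, np.pi**2 / 3.0))
        assert b.a == pytest.approx(1.0, abs=1e-8)
        assert b.b == pytest.approx(1.0, abs=1e-8)

    def test_forward_map_identities(self):
        pm = logit_moments_from_beta(BetaParams(1.0, 1.0))
        assert pm.mean == pytest.approx(0.0)
        assert pm.var == pytest.approx(np.pi**2 / 3.0)
        assert logit_moments_from_beta(BetaParams(4.2, 4.2)).mean == pytest.approx(0.0)
        # psi(2) = 1 + psi(1)
        assert logit_moments_from_beta(BetaParams(2.0, 1.0)).mean == pytest.approx(1.0)

    def test_sign_flip_swaps_parameters(self):
        b1 = beta_from_logit_moments(PredictorMoments(0.7, 1.1))
        b2 = beta_from_logit_moments(PredictorMoments(-0.7, 1.1))
        assert b1.a == pytest.approx(b2.b, rel=1e-8)
        assert b1.b == pytest.approx(b2.a, rel=1e-8)

    @pytest.mark.parametrize("a", [0.5, 1.0, 3.0, 7.0, 50.0])
    @pytest.mark.parametrize("b", [0.5, 2.0, 50.0])
    def test_round_trip_sweep(self, a, b):
        out = beta_from_logit_moments(logit_moments_from_beta(BetaParams(a, b)))
        assert out.a == pytest.approx(a, rel=1e-6, abs=1e-6)
        assert out.b == pytest.approx(b, rel=1e-6, abs=1e-6)

    def test_logit_moments_match_quadrature(self):
        """Digamma/trigamma formulas vs numerical integration over Beta."""
        a, b = 3.0, 7.0
        pm = logit_moments_from_beta(BetaParams(a, b))
        dist = stats.beta(a, b)
        m, _ = integrate.quad(lambda p: np.log(p / (1 - p)) * dist.pdf(p), 0, 1)
        m2, _ = integrate.quad(lambda p: np.log(p / (1 - p)) ** 2 * dist.pdf(p), 0, 1)
        assert pm.mean == pytest.approx(m, abs=1e-6)
        assert pm.var == pytest.approx(m2 - m * m, abs=1e-6)


class TestBernoulliUpdate:
    @pytest.mark.parametrize(
        "prior,x,expected",
        [
            ((1, 1), 1, (2, 1)),
            ((1, 1), 0, (1, 2)),
            ((3, 7), 1, (4, 7)),
        ],
    )
    def test_conjugacy(self, prior, x, expected):
        out = update_bernoulli(BetaParams(*prior), x)
        assert (out.a, out.b) == expected

    def test_domain(self):
        with pytest.raises(ValueError):
            update_bernoulli(BetaParams(1, 1), 2)


class TestGammaLogMatching:
    def test_unit_gamma_identities(self):
        pm = log_moments_from_gamma(GammaParams(1.0, 1.0))
        assert pm.mean == pytest.approx(-EULER, abs=1e-10)
        assert pm.var == pytest.approx(np.pi**2 / 6.0, abs=1e-10)
        g = gamma_from_log_moments(PredictorMoments(-EULER, np.pi**2 / 6.0))
        assert g.shape == pytest.approx(1.0, abs=1e-8)
        assert g.rate == pytest.approx(1.0, abs=1e-8)

    def test_psi_two_identity(self):
        assert log_moments_from_gamma(GammaParams(2.0, 1.0)).mean == pytest.approx(
            1.0 - EULER
        )

    def test_rate_scaling_shifts_log_mean(self):
        m1 = log_moments_from_gamma(GammaParams(4.0, 1.5)).mean
        m2 = log_moments_from_gamma(GammaParams(4.0, 3.0)).mean
        assert m1 - m2 == pytest.approx(math.log(2.0), abs=1e-12)

    @pytest.mark.parametrize("shape", [0.5, 1.0, 5.0, 50.0])
    @pytest.mark.parametrize("rate", [0.5, 2.0, 50.0])
    def test_round_trip_sweep(self, shape, rate):
        out = gamma_from_log_moments(log_moments_from_gamma(GammaParams(shape, rate)))
        assert out.shape == pytest.approx(shape, rel=1e-6)
        assert out.rate == pytest.approx(rate, rel=1e-6)

    def test_small_variance_concentrates(self):
        g = gamma_from_log_moments(PredictorMoments(0.0, 1e-4))
        assert g.shape > 1e3

    def test_log_moments_match_quadrature(self):
        shape, rate = 5.0, 2.0
        pm = log_moments_from_gamma(GammaParams(shape, rate))
        dist = stats.gamma(shape, scale=1.0 / rate)
        m, _ = integrate.quad(lambda e: np.log(e) * dist.pdf(e), 0, np.inf)
        m2, _ = integrate.quad(lambda e: np.log(e) ** 2 * dist.pdf(e), 0, np.inf)
        assert pm.mean == pytest.approx(m, abs=1e-6)
        assert pm.var == pytest.approx(m2 - m * m, abs=1e-6)


class TestPositiveCountUpdate:
    def test_conjugate_mode(self):
        out = update_positive_count(GammaParams(1, 1), 3)
        assert (out.shape, out.rate) == (4.0, 2.0)

    def test_repeated_ones(self):
        g = GammaParams(2.0, 3.0)
        for _ in range(5):
            g = update_positive_count(g, 1)
        assert (g.shape, g.rate) == (7.0, 8.0)

    def test_zero_rejected(self):
        with pytest.raises(ValueError, match="y >= 1"):
            update_positive_count(GammaParams(1, 1), 0)

    def test_exact_mode_close_to_conjugate_when_eta_large(self):
        conj = update_positive_count(GammaParams(5, 1), 4, mode="conjugate")
        exact = update_positive_count(GammaParams(5, 1), 4, mode="exact")
        d = abs(
            log_moments_from_gamma(conj).mean - log_moments_from_gamma(exact).mean
        )
        assert d < 0.1

    def test_exact_mode_matches_direct_quadrature(self):
        """Re-matched Gamma reproduces quadrature moments of the truncated
        posterior to 1e-6."""
        a, b, y = 2.0, 1.5, 2
        exact = update_positive_count(GammaParams(a, b), y, mode="exact")
        pm = log_moments_from_gamma(exact)

        def post(e):
            return e ** (a + y - 1) * np.exp(-(b + 1) * e) / (1 - np.exp(-e))

        z, _ = integrate.quad(post, 0, np.inf)
        m, _ = integrate.quad(lambda e: np.log(e) * post(e), 0, np.inf)
        m2, _ = integrate.quad(lambda e: np.log(e) ** 2 * post(e), 0, np.inf)
        assert pm.mean == pytest.approx(m / z, abs=1e-6)
        assert pm.var == pytest.approx(m2 / z - (m / z) ** 2, abs=1e-6)


class TestZeroTruncatedPoisson:
    def test_closed_form_at_log2(self):
        eta = math.log(2.0)
        assert ztp_pmf(1, eta) == pytest.approx(eta * 0.5 / 0.5)
        assert ztp_mean(eta) == pytest.approx(eta / 0.5)

    @pytest.mark.parametrize("eta", [0.1, 1.0, 3.0, 20.0])
    def test_normalizes(self, eta):
        y = np.arange(1, 201)
        assert ztp_pmf(y, eta).sum() == pytest.approx(1.0, abs=1e-12)

    def test_mean_formula(self):
        y = np.arange(1, 400)
        eta = 3.0
        assert (y * ztp_pmf(y, eta)).sum() == pytest.approx(ztp_mean(eta), abs=1e-12)

    def test_sampler_support_and_mean(self):
        rng = np.random.default_rng(11)
        draws = sample_ztp(np.full(20000, 0.5), rng)
        assert draws.min() >= 1
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - ztp_mean(0.5)) < 4 * se


class TestNIG:
    def test_predictor_moments_identities(self):
        mu_pm, logvar_pm = predictor_moments_from_nig(NIGParams(0, 1, 2, 1))
        assert (mu_pm.mean, mu_pm.var) == (0.0, 1.0)
        assert logvar_pm.mean == pytest.approx(-special.digamma(2.0))
        assert logvar_pm.var == pytest.approx(special.polygamma(1, 2.0))

    def test_location_shift_and_scale(self):
        mu1, lv1 = predictor_moments_from_nig(NIGParams(0.0, 1.0, 3.0, 2.0))
        mu2, lv2 = predictor_moments_from_nig(NIGParams(1.5, 1.0, 3.0, 2.0))
        assert mu2.mean - mu1.mean == pytest.approx(1.5)
        assert mu2.var == pytest.approx(mu1.var)
        _, lv3 = predictor_moments_from_nig(NIGParams(0.0, 1.0, 3.0, 4.0))
        assert lv3.mean - lv1.mean == pytest.approx(math.log(2.0))

    def test_round_trip(self):
        p = NIGParams(0.0, 1.0, 3.0, 2.0)
        out = nig_from_predictor_moments(*predictor_moments_from_nig(p))
        for name in ("m0", "c0", "a0", "b0"):
            assert getattr(out, name) == pytest.approx(getattr(p, name), rel=1e-6)

    def test_doubling_mu_var_halves_c0(self):
        mu_pm, lv_pm = predictor_moments_from_nig(NIGParams(0.5, 2.0, 3.0, 2.0))
        p1 = nig_from_predictor_moments(mu_pm, lv_pm)
        p2 = nig_from_predictor_moments(
            PredictorMoments(mu_pm.mean, 2.0 * mu_pm.var), lv_pm
        )
        assert p2.c0 == pytest.approx(p1.c0 / 2.0, rel=1e-8)
        assert p2.a0 == pytest.approx(p1.a0, rel=1e-8)
        assert p2.b0 == pytest.approx(p1.b0, rel=1e-8)

    def test_too_diffuse_logvar_fails(self):
        with pytest.raises(MomentMatchingError, match="a0"):
            nig_from_predictor_moments(
                PredictorMoments(0.0, 1.0), PredictorMoments(0.0, 2.0)
            )

    def test_logvar_moments_match_quadrature(self):
        """E/V of log sigma^2 under the inverse-gamma marginal."""
        p = NIGParams(0.0, 1.0, 3.0, 2.0)
        _, lv = predictor_moments_from_nig(p)
        dist = stats.invgamma(p.a0, scale=p.b0)
        m, _ = integrate.quad(lambda s: np.log(s) * dist.pdf(s), 0, np.inf)
        m2, _ = integrate.quad(lambda s: np.log(s) ** 2 * dist.pdf(s), 0, np.inf)
        assert lv.mean == pytest.approx(m, abs=1e-6)
        assert lv.var == pytest.approx(m2 - m * m, abs=1e-6)

    def test_mu_variance_matches_t_marginal(self):
        """V[mu] = b0/(c0 (a0-1)) equals the variance of the Student-t marginal."""
        p = NIGParams(0.3, 2.0, 4.0, 3.0)
        mu_pm, _ = predictor_moments_from_nig(p)
        t = stats.t(2 * p.a0, loc=p.m0, scale=math.sqrt(p.b0 / (p.a0 * p.c0)))
        assert mu_pm.var == pytest.approx(t.var(), rel=1e-10)


class TestGaussianUpdate:
    def test_standard_formulas(self):
        out = update_gaussian(NIGParams(0, 1, 2, 1), 2.0)
        assert (out.m0, out.c0, out.a0, out.b0) == (1.0, 2.0, 2.5, 2.0)

    def test_zero_residual_keeps_location(self):
        p = NIGParams(1.3, 2.0, 3.0, 1.5)
        out = update_gaussian(p, 1.3)
        assert out.m0 == pytest.approx(1.3)
        assert out.b0 == pytest.approx(1.5)

    def test_counting_fields_commute(self):
        p = NIGParams(0.0, 1.0, 2.0, 1.0)
        ab = update_gaussian(update_gaussian(p, 0.7), -1.1)
        ba = update_gaussian(update_gaussian(p, -1.1), 0.7)
        assert ab.c0 == ba.c0 == 3.0
        assert ab.a0 == ba.a0 == 3.0
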
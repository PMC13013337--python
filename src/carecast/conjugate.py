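"""Conjugate observation families and moment-matching maps.

The sequential learner never carries full posteriors in state space; instead
each observation family (Bernoulli occupancy, zero-truncated Poisson counts,
lognormal hours) talks to the state through the first two moments of its
*transformed* natural parameter:

* Bernoulli  —  Beta(a, b) prior on p, matched through moments of logit p:
  E[logit p] = psi(a) - psi(b),  V[logit p] = psi'(a) + psi'(b).
* positive counts —  Gamma(shape, rate) prior on eta, matched through log eta:
  E[log eta] = psi(shape) - log rate,  V[log eta] = psi'(shape).
* Gaussian with unknown variance —  Normal-Inverse-Gamma on (mu, sigma^2),
  matched through mu and log sigma^2.

psi / psi' are the digamma and trigamma functions; the inversions are
safeguarded Newton iterations on log-parameters (bracketing not needed as
the maps are monotone in the transformed coordinates), max 100 iterations,
residual tolerance 1e-10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

from .state import PredictorMoments

__all__ = [
    "MomentMatchingError",
    "BetaParams",
    "GammaParams",
    "NIGParams",
    "beta_from_logit_moments",
    "logit_moments_from_beta",
    "update_bernoulli",
    "gamma_from_log_moments",
    "log_moments_from_gamma",
    "update_positive_count",
    "ztp_pmf",
    "ztp_mean",
    "sample_ztp",
    "nig_from_predictor_moments",
    "predictor_moments_from_nig",
    "update_gaussian",
    "update_gaussian_known_var",
]

_MAX_ITER = 100
_TOL = 1e-10


class MomentMatchingError(RuntimeError):
    """Raised when a digamma/trigamma inversion fails to converge or the
    requested moments admit no valid parameter (e.g. NIG shape <= 1)."""


# --------------------------------------------------------------------------
# Beta <-> logit moments


@dataclass(frozen=True)
class BetaParams:
    """Beta(a, b) conjugate prior for an occupancy probability p."""

    a: float
    b: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", float(self.a))
        object.__setattr__(self, "b", float(self.b))
        if not (self.a > 0 and self.b > 0 and math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError(f"Beta parameters must be positive finite, got ({self.a}, {self.b})")

    def mean_p(self) -> float:
        return self.a / (self.a + self.b)

    def sd_p(self) -> float:
        s = self.a + self.b
        return math.sqrt(self.a * self.b / (s * s * (s + 1.0)))


@dataclass(frozen=True)
class GammaParams:
    """Gamma(shape, rate) conjugate prior for a positive-count intensity eta."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", float(self.shape))
        object.__setattr__(self, "rate", float(self.rate))
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError(
                f"Gamma parameters must be positive, got ({self.shape}, {self.rate})"
            )

    def mean(self) -> float:
        return self.shape / self.rate


@dataclass(frozen=True)
class NIGParams:
    """Normal-Inverse-Gamma prior for (mu, sigma^2): sigma^2 ~ IG(a0, b0),
    mu | sigma^2 ~ N(m0, sigma^2 / c0).  a0 > 1 keeps V[mu] finite."""

    m0: float
    c0: float
    a0: float
    b0: float

    def __post_init__(self) -> None:
        for name in ("m0", "c0", "a0", "b0"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not (self.c0 > 0 and self.b0 > 0):
            raise ValueError("NIG scale_count c0 and rate b0 must be positive")
        if not self.a0 > 1:
            raise ValueError(f"NIG shape a0 must exceed 1 for finite V[mu], got {self.a0}")


def logit_moments_from_beta(p: BetaParams) -> PredictorMoments:
    """Moments of logit p under Beta(a, b)."""
    return PredictorMoments(
        special.digamma(p.a) - special.digamma(p.b),
        special.polygamma(1, p.a) + special.polygamma(1, p.b),
    )


def beta_from_logit_moments(pm: PredictorMoments) -> BetaParams:
    """Invert (E, V) of logit p to Beta(a, b) by 2-D Newton on (log a, log b)."""
    if pm.var <= 0.0:
        raise MomentMatchingError("logit variance must be > 0 to match a Beta")
    m, v = pm.mean, pm.var
    # large-parameter asymptotics psi(a) ~ log a, psi'(a) ~ 1/a give the init
    a = max((1.0 + math.exp(min(m, 30.0))) / v, 1e-4)
    b = max((1.0 + math.exp(min(-m, 30.0))) / v, 1e-4)
    la, lb = math.log(a), math.log(b)
    for _ in range(_MAX_ITER):
        a, b = math.exp(la), math.exp(lb)
        f1 = special.digamma(a) - special.digamma(b) - m
        f2 = special.polygamma(1, a) + special.polygamma(1, b) - v
        if abs(f1) < _TOL and abs(f2) < _TOL * max(1.0, v):
            return BetaParams(a, b)
        ta, tb = special.polygamma(1, a), special.polygamma(1, b)
        qa, qb = special.polygamma(2, a), special.polygamma(2, b)
        # Jacobian in (la, lb)
        j11, j12 = ta * a, -tb * b
        j21, j22 = qa * a, qb * b
        det = j11 * j22 - j12 * j21
        if det == 0.0 or not math.isfinite(det):
            break
        dla = (f1 * j22 - f2 * j12) / det
        dlb = (j11 * f2 - j21 * f1) / det
        step = max(abs(dla), abs(dlb))
        damp = min(1.0, 2.0 / step) if step > 2.0 else 1.0
        la -= damp * dla
        lb -= damp * dlb
    a, b = math.exp(la), math.exp(lb)
    f1 = special.digamma(a) - special.digamma(b) - m
    f2 = special.polygamma(1, a) + special.polygamma(1, b) - v
    if abs(f1) < 1e-8 and abs(f2) < 1e-8 * max(1.0, v):
        return BetaParams(a, b)
    raise MomentMatchingError(
        f"Beta moment matching failed for mean={m:.4g}, var={v:.4g}"
    )


def update_bernoulli(prior: BetaParams, x: int) -> BetaParams:
    """One-observation Beta-Bernoulli conjugate update."""
    if x not in (0, 1):
        raise ValueError(f"Bernoulli observation must be 0 or 1, got {x!r}")
    return BetaParams(prior.a + x, prior.b + 1 - x)


# --------------------------------------------------------------------------
# Gamma <-> log moments


def _solve_trigamma(v: float) -> float:
    """Solve psi'(s) = v for s > 0 (trigamma is monotone decreasing)."""
    if v <= 0.0:
        raise MomentMatchingError("trigamma inversion needs a positive variance")
    # asymptotics psi'(s) ~ 1/s + 1/(2 s^2)
    s = max((1.0 + math.sqrt(1.0 + 2.0 * v)) / (2.0 * v), 1e-6)
    ls = math.log(s)
    for _ in range(_MAX_ITER):
        s = math.exp(ls)
        f = special.polygamma(1, s) - v
        if abs(f) < _TOL * max(1.0, v):
            return s
        df = special.polygamma(2, s) * s  # d/d(log s)
        step = f / df
        ls -= max(min(step, 2.0), -2.0)
    s = math.exp(ls)
    if abs(special.polygamma(1, s) - v) < 1e-8 * max(1.0, v):
        return s
    raise MomentMatchingError(f"trigamma inversion failed for variance {v:.4g}")


def log_moments_from_gamma(g: GammaParams) -> PredictorMoments:
    """Moments of log eta under Gamma(shape, rate)."""
    return PredictorMoments(
        special.digamma(g.shape) - math.log(g.rate),
        special.polygamma(1, g.shape),
    )


def gamma_from_log_moments(pm: PredictorMoments) -> GammaParams:
    """Invert (E, V) of log eta to Gamma(shape, rate)."""
    if pm.var <= 0.0:
        raise MomentMatchingError("log variance must be > 0 to match a Gamma")
    shape = _solve_trigamma(pm.var)
    rate = math.exp(special.digamma(shape) - pm.mean)
    return GammaParams(shape, rate)


def update_positive_count(
    prior: GammaParams, y: int, mode: str = "conjugate"
) -> GammaParams:
    """Update the Gamma intensity prior with one positive count.

    ``conjugate`` (default) applies the plain Gamma-Poisson update
    (shape + y, rate + 1), treating the positive count as Poisson evidence.
    ``exact`` accounts for the zero truncation: the posterior
    Gamma(eta; a, b) * eta^y e^{-eta} / (1 - e^{-eta}) is integrated by 1-D
    quadrature for the moments of log eta and a Gamma is re-matched to them.
    """
    if y < 1:
        raise ValueError(
            f"positive-count update needs y >= 1 (zeros go to the occupancy part), got {y}"
        )
    if mode == "conjugate":
        return GammaParams(prior.shape + y, prior.rate + 1.0)
    if mode != "exact":
        raise ValueError(f"mode must be 'conjugate' or 'exact', got {mode!r}")

    a, b = prior.shape, prior.rate

    def log_kernel(u: float) -> float:
        # u = log eta; includes Jacobian eta du
        eta = math.exp(u)
        return (a + y) * u - (b + 1.0) * eta - math.log1p(-math.exp(-eta))

    # centre the quadrature near the conjugate posterior mode
    centre = math.log((a + y) / (b + 1.0))
    shift = log_kernel(centre)

    def weight(u: float) -> float:
        return math.exp(log_kernel(u) - shift)

    lo, hi = centre - 20.0, centre + 10.0
    z, _ = integrate.quad(weight, lo, hi, limit=200)
    m1, _ = integrate.quad(lambda u: u * weight(u), lo, hi, limit=200)
    m2, _ = integrate.quad(lambda u: u * u * weight(u), lo, hi, limit=200)
    mean = m1 / z
    var = m2 / z - mean * mean
    return gamma_from_log_moments(PredictorMoments(mean, max(var, 1e-12)))


# --------------------------------------------------------------------------
# Zero-truncated Poisson

def ztp_pmf(y, eta):
    """Zero-truncated Poisson pmf: eta^y e^{-eta} / (y! (1 - e^{-eta})), y >= 1."""
    y = np.asarray(y)
    eta = np.asarray(eta, dtype=float)
    if np.any(eta <= 0):
        raise ValueError("ZTP intensity must be positive")
    out = np.where(
        y >= 1,
        stats.poisson.pmf(y, eta) / (-np.expm1(-eta)),
        0.0,
    )
    return out if out.ndim else float(out)


def ztp_mean(eta):
    """Mean of the zero-truncated Poisson: eta / (1 - e^{-eta})."""
    eta = np.asarray(eta, dtype=float)
    out = eta / (-np.expm1(-eta))
    return out if out.ndim else float(out)


def sample_ztp(eta, rng: np.random.Generator):
    """Draw zero-truncated Poisson variates by inverse-cdf conditioning.

    u is drawn uniformly on (P(Y=0), 1) so the Poisson quantile function
    lands on the positive support only.
    """
    eta = np.asarray(eta, dtype=float)
    p0 = np.exp(-eta)
    u = rng.uniform(size=eta.shape)
    draws = stats.poisson.ppf(p0 + u * (1.0 - p0), eta)
    return np.maximum(draws, 1.0).astype(np.int64)


# --------------------------------------------------------------------------
# Normal-Inverse-Gamma <-> (mu, log sigma^2) moments


def predictor_moments_from_nig(p: NIGParams) -> tuple[PredictorMoments, PredictorMoments]:
    """Moments of mu and of log sigma^2 implied by a NIG prior."""
    mu_pm = PredictorMoments(p.m0, p.b0 / (p.c0 * (p.a0 - 1.0)))
    logvar_pm = PredictorMoments(
        math.log(p.b0) - special.digamma(p.a0), special.polygamma(1, p.a0)
    )
    return mu_pm, logvar_pm


def nig_from_predictor_moments(
    mu_pm: PredictorMoments, logvar_pm: PredictorMoments
) -> NIGParams:
    """Match a NIG prior to moments of mu and of log sigma^2.

    a0 solves psi'(a0) = V[log sigma^2]; finite V[mu] requires a0 > 1, which
    fails when the log-variance is too diffuse (V >= psi'(1) = pi^2/6) — the
    caller may floor the log-variance variance and retry.
    """
    if mu_pm.var <= 0.0 or logvar_pm.var <= 0.0:
        raise MomentMatchingError("NIG matching needs positive variances")
    a0 = _solve_trigamma(logvar_pm.var)
    if a0 <= 1.0:
        raise MomentMatchingError(
            f"matched NIG shape a0={a0:.4g} <= 1: log-variance moments too diffuse"
        )
    b0 = math.exp(logvar_pm.mean + special.digamma(a0))
    c0 = b0 / ((a0 - 1.0) * mu_pm.var)
    return NIGParams(mu_pm.mean, c0, a0, b0)


def update_gaussian(prior: NIGParams, y: float) -> NIGParams:
    """One-observation NIG conjugate update for y ~ N(mu, sigma^2)."""
    y = float(y)
    m0, c0, a0, b0 = prior.m0, prior.c0, prior.a0, prior.b0
    return NIGParams(
        (c0 * m0 + y) / (c0 + 1.0),
        c0 + 1.0,
        a0 + 0.5,
        b0 + c0 * (y - m0) ** 2 / (2.0 * (c0 + 1.0)),
    )


def update_gaussian_known_var(
    prior: PredictorMoments, y: float, obs_var: float
) -> PredictorMoments:
    """Normal-Normal conjugate update for y ~ N(mu, obs_var) with known variance.

    The normal prior on mu is parameterized directly by its moments, so
    moment matching is the identity and the filtering cycle built on this
    family is exactly the local-level Kalman filter.
    """
    if obs_var <= 0.0:
        raise ValueError("observation variance must be positive")
    if prior.var == 0.0:
        return prior
    post_var = prior.var * obs_var / (prior.var + obs_var)
    post_mean = (obs_var * prior.mean + prior.var * float(y)) / (prior.var + obs_var)
    return PredictorMoments(post_mean, post_var)
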
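"""Lognormal dynamic GLM for daily caregiver-type staff hours.

log d_{r,t} ~ N(mu_{r,t}, sigma^2_{r,t}) with both mu and log sigma^2 given
their own linear predictors over evolving latent-state blocks.  The two
predictors are coupled through a Normal-Inverse-Gamma conjugate pair for
(mu, sigma^2): each day the predictor prior moments are matched to a NIG,
updated with the log observation, and the posterior moments of mu and of
log sigma^2 are split back into the two state blocks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import special, stats

from .conjugate import (
    MomentMatchingError,
    NIGParams,
    nig_from_predictor_moments,
    predictor_moments_from_nig,
    update_gaussian,
)
from .state import (
    LatentStateBelief,
    PredictorMoments,
    RegressionVector,
    StateEvolution,
    evolve_state,
    intercept_only,
    linear_bayes_update,
    predictor_prior,
)

__all__ = [
    "StaffTimeObservation",
    "DGLMState",
    "DGLMPredictive",
    "init_dglm_state",
    "dglm_one_step_params",
    "dglm_step",
    "dglm_sample_predictive",
    "dglm_one_step_interval",
]

logger = logging.getLogger(__name__)

# variance floor for the log-variance predictor when NIG matching fails
# (psi'(2) ~ 0.6449, so flooring at 0.64 pins the matched shape near 2)
_LOGVAR_VAR_FLOOR = 0.64
_DIFFUSE_EXTRA_VAR = 0.25


@dataclass(frozen=True)
class StaffTimeObservation:
    """One day's facility-wide hours for one caregiver type (RN/LPN/CNA)."""

    caregiver_type: str
    day: int
    hours: float

    def __post_init__(self) -> None:
        if not self.hours > 0:
            raise ValueError(
                f"hours must be positive (log scale), got {self.hours}; "
                "zero-total days are excluded from lognormal filtering"
            )


@dataclass(frozen=True)
class DGLMPredictive:
    """One-step predictive: NIG-mixed lognormal, i.e. location-scale Student-t
    on the log scale with df 2 a0, loc m0, scale sqrt(b0 (c0+1) / (a0 c0))."""

    nig: NIGParams

    @property
    def log_df(self) -> float:
        return 2.0 * self.nig.a0

    @property
    def log_loc(self) -> float:
        return self.nig.m0

    @property
    def log_scale(self) -> float:
        p = self.nig
        return math.sqrt(p.b0 * (p.c0 + 1.0) / (p.a0 * p.c0))

    def sample(self, n_samples: int, rng: np.random.Generator | int) -> np.ndarray:
        """Draw hours: sigma^2 ~ IG, mu | sigma^2 ~ N, y ~ N(mu, sigma^2), exp(y)."""
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        p = self.nig
        sigma2 = p.b0 / rng.gamma(p.a0, size=n_samples)
        mu = rng.normal(p.m0, np.sqrt(sigma2 / p.c0))
        y = rng.normal(mu, np.sqrt(sigma2))
        return np.exp(y)

    def interval(self, level: float = 0.9) -> tuple[float, float]:
        """Central predictive interval on the hours scale (exact t quantiles)."""
        alpha = 0.5 * (1.0 - level)
        lo, hi = stats.t.ppf([alpha, 1.0 - alpha], self.log_df,
                             loc=self.log_loc, scale=self.log_scale)
        return math.exp(lo), math.exp(hi)

    def median(self) -> float:
        return math.exp(self.log_loc)


@dataclass(frozen=True)
class DGLMState:
    """Latent-state blocks, covariates and evolutions for one caregiver type."""

    mean_state: LatentStateBelief
    logvar_state: LatentStateBelief
    mean_F: RegressionVector
    logvar_F: RegressionVector
    mean_evo: StateEvolution
    logvar_evo: StateEvolution

    def __post_init__(self) -> None:
        if self.mean_F.dim != self.mean_state.dim or self.mean_evo.dim != self.mean_state.dim:
            raise ValueError("mean block dimensions do not agree")
        if (
            self.logvar_F.dim != self.logvar_state.dim
            or self.logvar_evo.dim != self.logvar_state.dim
        ):
            raise ValueError("log-variance block dimensions do not agree")

    @property
    def day(self) -> int:
        return self.mean_state.time_index


def init_dglm_state(
    init_hours: np.ndarray | None = None,
    *,
    discount: float = 0.95,
    logvar_discount: float | None = None,
    n_extra: int = 0,
    day: int = 0,
) -> DGLMState:
    """Diffuse initial state equivalent to NIG(m0, c0=1, a0=2, b0=1).

    m0 is the mean of the first observed week's log hours when available,
    else 0.  Through the matching maps this NIG corresponds to predictor
    moments mu ~ (m0, 1) and log sigma^2 ~ (-psi(2), psi'(2)).
    """
    m0 = 0.0
    if init_hours is not None:
        head = np.asarray(init_hours, dtype=float)[:7]
        head = head[head > 0]
        if head.size:
            m0 = float(np.mean(np.log(head)))
    q = 1 + n_extra
    F = intercept_only() if n_extra == 0 else RegressionVector(
        np.r_[1.0, np.zeros(n_extra)],
        ("intercept",) + tuple(f"shared{i}" for i in range(n_extra)),
    )
    mean_evo = StateEvolution(np.eye(q), discount=discount)
    logvar_evo = StateEvolution(
        np.eye(q), discount=logvar_discount if logvar_discount is not None else discount
    )

    def block(mean0: float, var0: float) -> LatentStateBelief:
        mean = np.r_[mean0, np.zeros(n_extra)]
        cov = np.diag(np.r_[var0, np.full(n_extra, _DIFFUSE_EXTRA_VAR)])
        return LatentStateBelief(mean, cov, day)

    return DGLMState(
        mean_state=block(m0, 1.0),
        logvar_state=block(-float(special.digamma(2.0)), float(special.polygamma(1, 2.0))),
        mean_F=F,
        logvar_F=F,
        mean_evo=mean_evo,
        logvar_evo=logvar_evo,
    )


def _match_nig(mu_pm: PredictorMoments, logvar_pm: PredictorMoments) -> NIGParams:
    """NIG matching with the documented log-variance floor on failure."""
    try:
        return nig_from_predictor_moments(mu_pm, logvar_pm)
    except MomentMatchingError:
        logger.warning(
            "NIG matching failed at V[log sigma^2]=%.3g; flooring to %.3g",
            logvar_pm.var, _LOGVAR_VAR_FLOOR,
        )
        return nig_from_predictor_moments(
            mu_pm, PredictorMoments(logvar_pm.mean, _LOGVAR_VAR_FLOOR)
        )


def dglm_one_step_params(state: DGLMState) -> DGLMPredictive:
    """Evolve one day ahead and match the one-step NIG prior (pure)."""
    mean_prior = evolve_state(state.mean_state, state.mean_evo)
    logvar_prior = evolve_state(state.logvar_state, state.logvar_evo)
    nig = _match_nig(
        predictor_prior(mean_prior, state.mean_F),
        predictor_prior(logvar_prior, state.logvar_F),
    )
    return DGLMPredictive(nig)


def dglm_step(
    state: DGLMState,
    obs: StaffTimeObservation,
    *,
    mean_F: RegressionVector | None = None,
    logvar_F: RegressionVector | None = None,
) -> tuple[DGLMState, DGLMPredictive]:
    """Advance the filter by one observed day of staff hours.

    Returns the updated state and the predictive that was in force before
    the observation.  Optional covariate vectors override this day's F.
    """
    if obs.day != state.day + 1:
        raise ValueError(
            f"observation day {obs.day} does not follow state day {state.day}"
        )
    state = replace(
        state,
        mean_F=mean_F if mean_F is not None else state.mean_F,
        logvar_F=logvar_F if logvar_F is not None else state.logvar_F,
    )

    mean_prior = evolve_state(state.mean_state, state.mean_evo)
    logvar_prior = evolve_state(state.logvar_state, state.logvar_evo)
    nig = _match_nig(
        predictor_prior(mean_prior, state.mean_F),
        predictor_prior(logvar_prior, state.logvar_F),
    )
    predictive = DGLMPredictive(nig)

    nig_post = update_gaussian(nig, math.log(obs.hours))

    mu_prior_pm, logvar_prior_pm = predictor_moments_from_nig(nig)
    mu_post_pm, logvar_post_pm = predictor_moments_from_nig(nig_post)
    mean_post = linear_bayes_update(mean_prior, state.mean_F, mu_prior_pm, mu_post_pm)
    logvar_post = linear_bayes_update(
        logvar_prior, state.logvar_F, logvar_prior_pm, logvar_post_pm
    )

    return (
        replace(state, mean_state=mean_post, logvar_state=logvar_post),
        predictive,
    )


def dglm_sample_predictive(
    state: DGLMState, n_samples: int, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Sample the one-step predictive hours distribution from the current state."""
    return dglm_one_step_params(state).sample(n_samples, rng_seed)


def dglm_one_step_interval(state: DGLMState, level: float = 0.9) -> tuple[float, float]:
    """Central one-step predictive interval for hours at the given level."""
    return dglm_one_step_params(state).interval(level)
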
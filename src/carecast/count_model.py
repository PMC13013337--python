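"""Zero-augmented dynamic count model for daily group census (DCMM).

The observed volume z_{g,t} of acuity group g is modelled as a mixture: a
Bernoulli occupancy gate x_{g,t} ~ Ber(p_{g,t}) decides between a structural
zero and a zero-truncated Poisson draw with intensity eta_{g,t}.  Both
logit p and log eta are linear predictors over their own latent-state
blocks, which evolve day to day and are revised by the linear-Bayes cycle.

On a zero day only the occupancy block sees data; the intensity block still
evolves (its uncertainty inflates) but its conjugate parameters are not
updated — zeros carry no information about the positive-count intensity in
this factorization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .conjugate import (
    BetaParams,
    GammaParams,
    MomentMatchingError,
    beta_from_logit_moments,
    gamma_from_log_moments,
    logit_moments_from_beta,
    log_moments_from_gamma,
    sample_ztp,
    update_bernoulli,
    update_positive_count,
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
    "CountObservation",
    "DCMMState",
    "DCMMPredictive",
    "init_dcmm_state",
    "dcmm_one_step_params",
    "dcmm_step",
    "dcmm_sample_predictive",
]

logger = logging.getLogger(__name__)

# logit-p prior moments equivalent to Beta(1, 1); log-eta variance 1 matches a
# weakly informative Gamma through the trigamma inversion
_BERN_INIT = PredictorMoments(0.0, np.pi**2 / 3.0)
_DIFFUSE_EXTRA_VAR = 0.25  # prior variance of appended shared-covariate effects


@dataclass(frozen=True)
class CountObservation:
    """One day's resident count for one acuity group."""

    group: str
    day: int
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be non-negative, got {self.count}")


@dataclass(frozen=True)
class DCMMPredictive:
    """One-step predictive law: Beta-mixed occupancy times Gamma-mixed ZTP."""

    bern: BetaParams
    pois: GammaParams

    def sample(self, n_samples: int, rng: np.random.Generator | int) -> np.ndarray:
        """Draw n_samples counts: p ~ Beta, x ~ Ber(p); if x=1, eta ~ Gamma, z ~ ZTP(eta)."""
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        p = rng.beta(self.bern.a, self.bern.b, size=n_samples)
        x = rng.uniform(size=n_samples) < p
        out = np.zeros(n_samples, dtype=np.int64)
        n_pos = int(x.sum())
        if n_pos:
            eta = rng.gamma(self.pois.shape, 1.0 / self.pois.rate, size=n_pos)
            out[x] = sample_ztp(eta, rng)
        return out


@dataclass(frozen=True)
class DCMMState:
    """Latent-state blocks, covariates and evolutions for one group's DCMM."""

    bern_state: LatentStateBelief
    pois_state: LatentStateBelief
    bern_F: RegressionVector
    pois_F: RegressionVector
    bern_evo: StateEvolution
    pois_evo: StateEvolution

    def __post_init__(self) -> None:
        if self.bern_F.dim != self.bern_state.dim or self.bern_evo.dim != self.bern_state.dim:
            raise ValueError("occupancy block dimensions do not agree")
        if self.pois_F.dim != self.pois_state.dim or self.pois_evo.dim != self.pois_state.dim:
            raise ValueError("intensity block dimensions do not agree")

    @property
    def day(self) -> int:
        return self.bern_state.time_index


def init_dcmm_state(
    init_counts: np.ndarray | None = None,
    *,
    discount: float = 0.95,
    n_extra: int = 0,
    day: int = 0,
) -> DCMMState:
    """Diffuse initial state.

    The occupancy predictor starts at the Beta(1, 1) equivalent
    (mean 0, variance pi^2/3 on the logit scale); the intensity predictor
    starts at the log of the mean positive count over the first observed
    week when ``init_counts`` is given (variance 1), else at 0.

    ``n_extra`` appends that many shared-covariate effect entries with mean 0
    and weakly informative variance to both blocks.
    """
    log_level = 0.0
    if init_counts is not None:
        head = np.asarray(init_counts, dtype=float)[:7]
        pos = head[head > 0]
        if pos.size:
            log_level = float(np.log(pos.mean()))
    q = 1 + n_extra
    F = intercept_only() if n_extra == 0 else RegressionVector(
        np.r_[1.0, np.zeros(n_extra)],
        ("intercept",) + tuple(f"shared{i}" for i in range(n_extra)),
    )
    evo = StateEvolution(np.eye(q), discount=discount)

    def block(mean0: float, var0: float) -> LatentStateBelief:
        mean = np.r_[mean0, np.zeros(n_extra)]
        cov = np.diag(np.r_[var0, np.full(n_extra, _DIFFUSE_EXTRA_VAR)])
        return LatentStateBelief(mean, cov, day)

    return DCMMState(
        bern_state=block(_BERN_INIT.mean, _BERN_INIT.var),
        pois_state=block(log_level, 1.0),
        bern_F=F,
        pois_F=F,
        bern_evo=evo,
        pois_evo=evo,
    )


def _match_with_inflation(match, pm: PredictorMoments, label: str):
    """Run a moment-matching map, inflating the variance on failure.

    Matching can fail for extreme moments reached late in long recursions;
    the fallback inflates the variance by 1.5x (up to 5 times) which only
    makes the prior more diffuse, never more confident.
    """
    var = pm.var
    for attempt in range(6):
        try:
            return match(PredictorMoments(pm.mean, var))
        except MomentMatchingError:
            if attempt == 5:
                raise
            var *= 1.5
            logger.warning(
                "%s moment matching failed at var=%.3g; inflating to %.3g",
                label, var / 1.5, var,
            )


def dcmm_one_step_params(state: DCMMState) -> DCMMPredictive:
    """Evolve one day ahead and match the conjugate one-step priors (pure)."""
    bern_prior = evolve_state(state.bern_state, state.bern_evo)
    pois_prior = evolve_state(state.pois_state, state.pois_evo)
    beta = _match_with_inflation(
        beta_from_logit_moments, predictor_prior(bern_prior, state.bern_F), "Beta"
    )
    gamma = _match_with_inflation(
        gamma_from_log_moments, predictor_prior(pois_prior, state.pois_F), "Gamma"
    )
    return DCMMPredictive(beta, gamma)


def dcmm_step(
    state: DCMMState,
    obs: CountObservation,
    *,
    update_mode: str = "conjugate",
    bern_F: RegressionVector | None = None,
    pois_F: RegressionVector | None = None,
) -> tuple[DCMMState, DCMMPredictive]:
    """Advance the filter by one observed day.

    Returns the updated state and the one-step predictive that was in force
    *before* the observation arrived (for honest forecast evaluation).
    Optional ``bern_F`` / ``pois_F`` replace the covariate vectors for this
    day (time-varying covariates, e.g. shared-information augmentation).
    """
    if obs.count < 0:
        raise ValueError("count must be non-negative")
    if obs.day != state.day + 1:
        raise ValueError(
            f"observation day {obs.day} does not follow state day {state.day}"
        )
    state = replace(
        state,
        bern_F=bern_F if bern_F is not None else state.bern_F,
        pois_F=pois_F if pois_F is not None else state.pois_F,
    )

    bern_prior = evolve_state(state.bern_state, state.bern_evo)
    pois_prior = evolve_state(state.pois_state, state.pois_evo)
    beta = _match_with_inflation(
        beta_from_logit_moments, predictor_prior(bern_prior, state.bern_F), "Beta"
    )
    gamma = _match_with_inflation(
        gamma_from_log_moments, predictor_prior(pois_prior, state.pois_F), "Gamma"
    )
    predictive = DCMMPredictive(beta, gamma)

    # occupancy block always sees the indicator
    x = 1 if obs.count > 0 else 0
    beta_post = update_bernoulli(beta, x)
    bern_post = linear_bayes_update(
        bern_prior,
        state.bern_F,
        logit_moments_from_beta(beta),
        logit_moments_from_beta(beta_post),
    )

    if obs.count > 0:
        gamma_post = update_positive_count(gamma, obs.count, mode=update_mode)
        pois_post = linear_bayes_update(
            pois_prior,
            state.pois_F,
            log_moments_from_gamma(gamma),
            log_moments_from_gamma(gamma_post),
        )
    else:
        pois_post = pois_prior  # evolves (variance inflated) but no data update

    return replace(state, bern_state=bern_post, pois_state=pois_post), predictive


def dcmm_sample_predictive(
    state: DCMMState, n_samples: int, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Sample the one-step predictive count distribution from the current state."""
    return dcmm_one_step_params(state).sample(n_samples, rng_seed)
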
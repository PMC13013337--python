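"""Linear-Bayes state-space core shared by the count and staff-time models.

Each linear predictor of each series carries its own latent-state block
``theta_t`` with belief (m, V).  The filtering cycle is

    evolve_state  ->  predictor_prior  ->  conjugate update  ->  linear_bayes_update

i.e. propagate the state belief one day forward, project it onto the linear
predictor ``phi = F' theta``, update the predictor moments through the
conjugate observation family, and push the revised moments back into the
state by a linear-Bayes (Kalman-style) regression step that uses only first
and second moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LatentStateBelief",
    "StateEvolution",
    "RegressionVector",
    "PredictorMoments",
    "intercept_only",
    "evolve_state",
    "predictor_prior",
    "linear_bayes_update",
]


def _symmetrize_psd(cov: np.ndarray) -> np.ndarray:
    """Symmetrize and clip tiny negative eigenvalues (float-drift guard)."""
    cov = 0.5 * (cov + cov.T)
    if cov.shape[0] == 1:
        return np.maximum(cov, 0.0)
    if np.linalg.eigvalsh(cov)[0] >= 0.0:
        return cov
    w, Q = np.linalg.eigh(cov)
    repaired = (Q * np.clip(w, 0.0, None)) @ Q.T
    return 0.5 * (repaired + repaired.T)


@dataclass(frozen=True)
class LatentStateBelief:
    """Mean/covariance belief about one latent state block at day ``time_index``."""

    mean: np.ndarray
    cov: np.ndarray
    time_index: int = 0

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if mean.ndim != 1:
            raise ValueError("mean must be a vector")
        if cov.shape != (mean.size, mean.size):
            raise ValueError(
                f"cov shape {cov.shape} does not match state dimension {mean.size}"
            )
        if not np.all(np.isfinite(mean)) or not np.all(np.isfinite(cov)):
            raise ValueError("state belief must be finite")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("cov must be symmetric")
        if np.linalg.eigvalsh(0.5 * (cov + cov.T))[0] < -1e-10 * max(
            1.0, float(np.abs(cov).max())
        ):
            raise ValueError("cov must be positive semi-definite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", 0.5 * (cov + cov.T))

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class StateEvolution:
    """Day-to-day state transition: theta_t = G theta_{t-1} + w_t.

    Exactly one of ``noise_cov`` (W) and ``discount`` may be given; under a
    discount factor delta the evolution noise is the standard construction
    W = ((1-delta)/delta) G V G', i.e. the propagated covariance is G V G'/delta.
    """

    transition: np.ndarray
    noise_cov: np.ndarray | None = None
    discount: float | None = None

    def __post_init__(self) -> None:
        G = np.atleast_2d(np.asarray(self.transition, dtype=float))
        if G.shape[0] != G.shape[1]:
            raise ValueError("transition matrix must be square")
        object.__setattr__(self, "transition", G)
        if (self.noise_cov is None) == (self.discount is None):
            raise ValueError("exactly one of noise_cov / discount must be set")
        if self.noise_cov is not None:
            W = np.atleast_2d(np.asarray(self.noise_cov, dtype=float))
            if W.shape != G.shape:
                raise ValueError("noise_cov shape must match transition")
            if not np.allclose(W, W.T, atol=1e-8):
                raise ValueError("noise_cov must be symmetric")
            object.__setattr__(self, "noise_cov", 0.5 * (W + W.T))
        else:
            d = float(self.discount)
            if not (0.0 < d <= 1.0):
                raise ValueError(f"discount must lie in (0, 1], got {d}")
            object.__setattr__(self, "discount", d)

    @property
    def dim(self) -> int:
        return self.transition.shape[0]


@dataclass(frozen=True)
class RegressionVector:
    """Covariate vector F_t pairing with a latent-state block.

    By convention the first entry is the intercept (value 1) in the shipped
    default F = (1,).
    """

    values: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        if v.ndim != 1:
            raise ValueError("regression vector must be 1-D")
        names = tuple(self.names) if self.names else tuple(f"x{i}" for i in range(v.size))
        if len(names) != v.size:
            raise ValueError("names length must match values length")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "names", names)

    @property
    def dim(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PredictorMoments:
    """Mean and variance of one transformed parameter (logit p, log eta, mu, log sigma^2)."""

    mean: float
    var: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", float(self.mean))
        object.__setattr__(self, "var", float(self.var))
        if not np.isfinite(self.mean) or not np.isfinite(self.var):
            raise ValueError("predictor moments must be finite")
        if self.var < 0.0:
            raise ValueError(f"predictor variance must be >= 0, got {self.var}")


def intercept_only() -> RegressionVector:
    """The shipped default covariate vector F = (1,)."""
    return RegressionVector(np.array([1.0]), ("intercept",))


def evolve_state(post: LatentStateBelief, evo: StateEvolution) -> LatentStateBelief:
    """Propagate a posterior belief at t-1 to the prior at t.

    Returns the belief with mean ``G m`` and covariance ``G V G' + W``;
    with a discount factor the covariance is ``G V G' / delta``.
    """
    if evo.dim != post.dim:
        raise ValueError(
            f"evolution dimension {evo.dim} does not match state dimension {post.dim}"
        )
    G = evo.transition
    mean = G @ post.mean
    prop = G @ post.cov @ G.T
    if evo.discount is not None:
        cov = prop / evo.discount
    else:
        cov = prop + evo.noise_cov
    return LatentStateBelief(mean, _symmetrize_psd(cov), post.time_index + 1)


def predictor_prior(prior: LatentStateBelief, F: RegressionVector) -> PredictorMoments:
    """Project a state belief onto the linear predictor: (F'm, F'VF)."""
    if F.dim != prior.dim:
        raise ValueError(
            f"regression vector length {F.dim} does not match state dimension {prior.dim}"
        )
    f = F.values
    mean = float(f @ prior.mean)
    var = float(f @ prior.cov @ f)
    return PredictorMoments(mean, max(var, 0.0))


def linear_bayes_update(
    prior: LatentStateBelief,
    F: RegressionVector,
    prior_pm: PredictorMoments,
    post_pm: PredictorMoments,
) -> LatentStateBelief:
    """Push revised predictor moments back into the state block.

    m_t = m + V F (m_post - m_prior) / V_prior
    V_t = V - V F F' V (1 - V_post/V_prior) / V_prior

    The posterior covariance is symmetrized and tiny negative eigenvalues are
    clipped to zero to guard against float drift in long recursions.
    """
    if F.dim != prior.dim:
        raise ValueError("regression vector length does not match state dimension")
    if prior_pm.var <= 0.0:
        raise ValueError(
            "degenerate predictor prior: variance must be > 0 for a linear-Bayes update"
        )
    f = F.values
    Vf = prior.cov @ f
    mean = prior.mean + Vf * ((post_pm.mean - prior_pm.mean) / prior_pm.var)
    shrink = (1.0 - post_pm.var / prior_pm.var) / prior_pm.var
    cov = prior.cov - np.outer(Vf, Vf) * shrink
    return LatentStateBelief(mean, _symmetrize_psd(cov), prior.time_index)
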
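"""Multi-step recursive forecasting, rolling-origin evaluation, and metrics.

One-step-ahead forecasts come straight from the filtered predictive law.
For horizons k >= 2 the default *recursive* scheme feeds the point forecast
(the sample median) back into the update machinery as a pseudo-observation
and rolls the state forward; the *marginal* alternative evolves the states
without any data update so predictive uncertainty diffuses freely.

The rolling harness mirrors the evaluation protocol of re-anchoring the
forecast origin every window: forecast a window ahead, ingest the actually
observed window, and repeat until the horizon is covered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .count_model import (
    CountObservation,
    DCMMState,
    dcmm_one_step_params,
    dcmm_step,
    init_dcmm_state,
)
from .hours_model import (
    DGLMState,
    StaffTimeObservation,
    dglm_one_step_params,
    dglm_step,
    init_dglm_state,
)
from .shared import SharedInfoConfig, augment_regression
from .state import RegressionVector, evolve_state

__all__ = [
    "ForecastDistribution",
    "EvaluationReport",
    "lower_median",
    "compute_metrics",
    "forecast_horizon",
    "filter_count_series",
    "filter_hours_series",
    "rolling_forecast",
    "RollingResult",
]


def lower_median(samples: np.ndarray, axis: int = 0) -> np.ndarray | float:
    """Median as the ceil(n/2)-th order statistic (lower median for even n).

    Using an order statistic rather than the midpoint average keeps count
    forecasts integer-valued and the n=1000 protocol bit-exact.
    """
    samples = np.asarray(samples)
    n = samples.shape[axis]
    k = (n + 1) // 2 - 1
    out = np.take(np.sort(samples, axis=axis), k, axis=axis)
    return out


@dataclass(frozen=True)
class ForecastDistribution:
    """Predictive sample paths over a horizon with point/interval summaries."""

    samples: np.ndarray  # (n_samples, horizon)
    origin_day: int
    point: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        samples = np.atleast_2d(np.asarray(self.samples))
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "point", lower_median(samples, axis=0))

    @property
    def horizon(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def interval(self, level: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
        """Central predictive interval per day at the given level."""
        alpha = 0.5 * (1.0 - level)
        lo = np.quantile(self.samples, alpha, axis=0)
        hi = np.quantile(self.samples, 1.0 - alpha, axis=0)
        return lo, hi


@dataclass(frozen=True)
class EvaluationReport:
    """MAE / MAPE / RMSE over a forecast horizon.

    MAPE averages |e_k| / x_k over days with x_k != 0 only;
    ``n_mape_excluded`` counts the zero-observation days left out, and MAPE
    is NaN when every day was zero.
    """

    mae: float
    mape: float
    rmse: float
    horizon: int
    n_days: int
    n_mape_excluded: int = 0

    def __post_init__(self) -> None:
        if self.mae < 0 or self.rmse < 0 or (not math.isnan(self.mape) and self.mape < 0):
            raise ValueError("error metrics must be non-negative")
        if self.rmse + 1e-12 < self.mae:
            raise ValueError("RMSE cannot be smaller than MAE")


def compute_metrics(obs, pred) -> EvaluationReport:
    """Score point forecasts against observations (e_k = x_k - xhat_k)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 1:
        raise ValueError("obs and pred must be equal-length 1-D with K >= 1")
    err = obs - pred
    K = obs.size
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    nz = obs != 0
    with np.errstate(over="ignore"):  # |e|/|x| may overflow for denormal x
        mape = (
            float((np.abs(err[nz]) / np.abs(obs[nz])).mean()) if nz.any() else float("nan")
        )
    return EvaluationReport(
        mae=mae,
        mape=mape,
        rmse=rmse,
        horizon=K,
        n_days=K,
        n_mape_excluded=int((~nz).sum()),
    )


# --------------------------------------------------------------------------
# model adapters: one code path for DCMM and DGLM states


def _is_count(state) -> bool:
    if isinstance(state, DCMMState):
        return True
    if isinstance(state, DGLMState):
        return False
    raise TypeError(f"unsupported model state {type(state).__name__}")


def _one_step(state, F=None):
    if _is_count(state):
        if F is not None:
            state = replace(state, bern_F=F, pois_F=F)
        return dcmm_one_step_params(state)
    if F is not None:
        state = replace(state, mean_F=F, logvar_F=F)
    return dglm_one_step_params(state)


def _step(state, value: float, F=None):
    if _is_count(state):
        obs = CountObservation("*", state.day + 1, int(round(value)))
        return dcmm_step(state, obs, bern_F=F, pois_F=F)
    obs = StaffTimeObservation("*", state.day + 1, float(value))
    return dglm_step(state, obs, mean_F=F, logvar_F=F)


def _evolve_only(state):
    if _is_count(state):
        return replace(
            state,
            bern_state=evolve_state(state.bern_state, state.bern_evo),
            pois_state=evolve_state(state.pois_state, state.pois_evo),
        )
    return replace(
        state,
        mean_state=evolve_state(state.mean_state, state.mean_evo),
        logvar_state=evolve_state(state.logvar_state, state.logvar_evo),
    )


def forecast_horizon(
    state: DCMMState | DGLMState,
    K: int,
    n_samples: int = 1000,
    seed: int | np.random.Generator = 0,
    mode: str = "recursive",
) -> ForecastDistribution:
    """Forecast K days ahead from a filtered state (the state is not mutated).

    k=1 is the current one-step predictive.  In ``recursive`` mode each
    further day feeds the running sample-median point forecast back as a
    pseudo-observation (earlier pseudo-observations persist in the state);
    ``marginal`` mode evolves the states without data updates instead.
    """
    if K < 1:
        raise ValueError(f"horizon K must be >= 1, got {K}")
    if mode not in ("recursive", "marginal"):
        raise ValueError(f"mode must be 'recursive' or 'marginal', got {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    origin = state.day
    samples = np.empty((n_samples, K))
    cur = state
    for k in range(K):
        pred = _one_step(cur)
        draws = pred.sample(n_samples, rng)
        samples[:, k] = draws
        if k < K - 1:
            if mode == "recursive":
                cur, _ = _step(cur, float(lower_median(draws)))
            else:
                cur = _evolve_only(cur)
    return ForecastDistribution(samples, origin_day=origin)


# --------------------------------------------------------------------------
# multi-series filtering with optional shared-information augmentation


@dataclass
class FilterResult:
    """Filtered states, running one-step point forecasts, optional trace.

    The trace records, per day and series, the one-step predictor moments
    and matched conjugate parameters that were in force before the update —
    the quantities a downstream audit of the filter needs.
    """

    states: dict[str, DCMMState | DGLMState]
    one_step_points: pd.DataFrame | None
    history: pd.DataFrame
    trace: list[dict] | None = None


def _trace_row(day: int, label: str, pred) -> dict:
    from .count_model import DCMMPredictive

    if isinstance(pred, DCMMPredictive):
        from .conjugate import log_moments_from_gamma, logit_moments_from_beta

        lp, le = logit_moments_from_beta(pred.bern), log_moments_from_gamma(pred.pois)
        return {
            "day": day, "series": label,
            "occupancy_a": pred.bern.a, "occupancy_b": pred.bern.b,
            "intensity_shape": pred.pois.shape, "intensity_rate": pred.pois.rate,
            "logit_p_mean": lp.mean, "logit_p_var": lp.var,
            "log_eta_mean": le.mean, "log_eta_var": le.var,
        }
    p = pred.nig
    return {
        "day": day, "series": label,
        "m0": p.m0, "c0": p.c0, "a0": p.a0, "b0": p.b0,
        "mu_mean": p.m0, "mu_var": p.b0 / (p.c0 * (p.a0 - 1.0)),
    }


def _covariate_history(df: pd.DataFrame, count_model: bool) -> pd.DataFrame:
    """Series fed into the shared covariates: raw counts, or log hours."""
    if count_model:
        return df.astype(float)
    logged = np.log(df.where(df > 0))
    return logged.ffill().fillna(0.0)


def _filter_series(
    df: pd.DataFrame,
    count_model: bool,
    *,
    discount: float = 0.95,
    shared: SharedInfoConfig | None = None,
    update_mode: str = "conjugate",
    n_samples: int = 0,
    seed: int | np.random.Generator = 0,
    init_from_head: bool = True,
    trace: bool = False,
) -> FilterResult:
    labels = list(df.columns)
    if shared is not None:
        missing = set(labels) - set(shared.labels)
        if missing:
            raise KeyError(f"labels {sorted(missing)} not covered by shared clusters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    states: dict[str, DCMMState | DGLMState] = {}
    for lab in labels:
        n_extra = 1 if shared is not None and shared.partners_of(lab) else 0
        head = df[lab].to_numpy() if init_from_head else None
        if count_model:
            states[lab] = init_dcmm_state(head, discount=discount, n_extra=n_extra)
        else:
            states[lab] = init_dglm_state(head, discount=discount, n_extra=n_extra)

    points = (
        pd.DataFrame(np.nan, index=df.index, columns=labels) if n_samples > 0 else None
    )
    cov_hist = _covariate_history(df, count_model)
    trace_rows: list[dict] | None = [] if trace else None

    for t in range(len(df)):
        attained = cov_hist.iloc[:t]
        for lab in labels:
            state = states[lab]
            F = None
            if shared is not None and shared.partners_of(lab):
                base = replace_intercept_base(state)
                F = augment_regression(base, lab, shared, attained)
            value = df.iloc[t][lab]
            if not count_model and not value > 0:
                # log undefined: the lognormal filter skips the day but the
                # state still evolves to stay calendar-aligned
                if n_samples > 0 or trace:
                    pred = _one_step(state, F)
                    if n_samples > 0:
                        points.iloc[t, points.columns.get_loc(lab)] = float(
                            lower_median(pred.sample(n_samples, rng))
                        )
                    if trace:
                        trace_rows.append(_trace_row(t, lab, pred))
                states[lab] = _evolve_only(state)
                continue
            new_state, pred = _step(state, float(value), F)
            if n_samples > 0:
                points.iloc[t, points.columns.get_loc(lab)] = float(
                    lower_median(pred.sample(n_samples, rng))
                )
            if trace:
                trace_rows.append(_trace_row(t, lab, pred))
            states[lab] = new_state

    return FilterResult(
        states=states, one_step_points=points, history=df, trace=trace_rows
    )


def filter_count_series(df: pd.DataFrame, **kwargs) -> FilterResult:
    """Filter every group's census series (DCMM; DCMM_S when ``shared`` given).

    ``df`` is wide-format: one row per consecutive day, one column per group.
    With ``n_samples`` > 0 the one-step point forecast (sample lower-median,
    computed before each day's update) is recorded per day.
    """
    return _filter_series(df, True, **kwargs)


def filter_hours_series(df: pd.DataFrame, **kwargs) -> FilterResult:
    """Filter every caregiver type's hours series (DGLM / DGLM_S).

    Days with non-positive hours are skipped by the lognormal update (the
    state evolves without data) and logged in the result's history.
    """
    return _filter_series(df, False, **kwargs)


def replace_intercept_base(state):
    """Base (intercept-only prefix) regression vector of an augmented state."""
    F = state.bern_F if _is_count(state) else state.mean_F
    return RegressionVector(F.values[:-1], F.names[:-1])


@dataclass
class RollingResult:
    """Forecasts and scores from a rolling-origin evaluation."""

    forecasts: dict[str, list[ForecastDistribution]]
    points: pd.DataFrame
    reports: dict[str, EvaluationReport]
    origins: list[int]


def rolling_forecast(
    data: pd.DataFrame,
    train_end,
    horizon_days: int,
    window_days: int,
    n_samples: int = 1000,
    seed: int = 0,
    *,
    model: str = "dcmm",
    shared: SharedInfoConfig | None = None,
    discount: float = 0.95,
    mode: str = "recursive",
) -> RollingResult:
    """Rolling-origin multi-step forecasting over ``horizon_days``.

    Filter on the training span, then at each window origin forecast
    ``window_days`` ahead (jointly across columns when shared covariates are
    on, feeding point forecasts into the pseudo-history), ingest the actually
    observed window, and roll.  ``train_end`` is either the number of
    training days or a label into ``data.index`` marking the last training
    row (inclusive).  Point forecasts over the horizon are scored per column.
    """
    count_model = model in ("dcmm", "dcmm_s")
    if model not in ("dcmm", "dcmm_s", "dglm", "dglm_s"):
        raise ValueError(f"unknown model {model!r}")
    if model.endswith("_s") and shared is None:
        raise ValueError(f"model {model!r} needs a SharedInfoConfig")
    if not model.endswith("_s"):
        shared = None

    if isinstance(train_end, (int, np.integer)):
        n_train = int(train_end)
    else:
        n_train = int(data.index.get_loc(train_end)) + 1
    if n_train < 1 or n_train + horizon_days > len(data):
        raise ValueError(
            f"data has {len(data)} rows: cannot train on {n_train} and "
            f"forecast {horizon_days} more"
        )

    rng = np.random.default_rng(seed)
    labels = list(data.columns)
    res = _filter_series(
        data.iloc[:n_train], count_model,
        discount=discount, shared=shared, seed=rng,
    )
    states = res.states
    cov_hist_full = _covariate_history(data, count_model)

    origins: list[int] = []
    fc_per_label: dict[str, list[ForecastDistribution]] = {lab: [] for lab in labels}
    point_rows: list[np.ndarray] = []

    pos = n_train
    while pos < n_train + horizon_days:
        origins.append(pos)
        w = min(window_days, n_train + horizon_days - pos)
        # joint forecast of this window
        window_samples = {lab: np.empty((n_samples, w)) for lab in labels}
        fc_states = dict(states)
        pseudo_hist = cov_hist_full.iloc[:pos].copy()
        for k in range(w):
            row_points = {}
            for lab in labels:
                state = fc_states[lab]
                F = None
                if shared is not None and shared.partners_of(lab):
                    base = replace_intercept_base(state)
                    F = augment_regression(base, lab, shared, pseudo_hist)
                pred = _one_step(state, F)
                draws = pred.sample(n_samples, rng)
                window_samples[lab][:, k] = draws
                point = float(lower_median(draws))
                row_points[lab] = point
                if mode == "recursive":
                    fc_states[lab], _ = _step(state, point, F)
                else:
                    fc_states[lab] = _evolve_only(state)
            # pseudo-observations extend the covariate history for the next day
            if count_model:
                pseudo_row = {lab: float(row_points[lab]) for lab in labels}
            else:
                pseudo_row = {
                    lab: float(np.log(max(row_points[lab], 1e-12))) for lab in labels
                }
            pseudo_hist.loc[len(pseudo_hist)] = pseudo_row
            point_rows.append(np.array([row_points[lab] for lab in labels]))
        for lab in labels:
            fc_per_label[lab].append(
                ForecastDistribution(window_samples[lab], origin_day=states[lab].day)
            )
        # ingest the actually observed window, then roll
        obs_window = data.iloc[pos : pos + w]
        for t in range(len(obs_window)):
            attained = cov_hist_full.iloc[: pos + t]
            for lab in labels:
                state = states[lab]
                F = None
                if shared is not None and shared.partners_of(lab):
                    base = replace_intercept_base(state)
                    F = augment_regression(base, lab, shared, attained)
                value = obs_window.iloc[t][lab]
                if not count_model and not value > 0:
                    states[lab] = _evolve_only(state)
                    continue
                states[lab], _ = _step(state, float(value), F)
        pos += w

    horizon_index = data.index[n_train : n_train + horizon_days]
    points = pd.DataFrame(point_rows, index=horizon_index, columns=labels)
    reports = {
        lab: compute_metrics(
            data[lab].iloc[n_train : n_train + horizon_days].to_numpy(dtype=float),
            points[lab].to_numpy(),
        )
        for lab in labels
    }
    return RollingResult(
        forecasts=fc_per_label, points=points, reports=reports, origins=origins
    )
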
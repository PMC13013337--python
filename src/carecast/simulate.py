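"""Synthetic service-need data with the structure the models assume.

Two levels of generator:

* :func:`simulate_series` draws daily group counts and staff hours directly
  from the generative model — drifting/oscillating latent paths for the
  occupancy logit and the log intensity, a Bernoulli gate, zero-truncated
  Poisson counts, and linear staffing aggregation with lognormal
  perturbation — returning the latent truth for recovery tests.
* :func:`simulate_residents` emits resident-level assessment records
  (admissions, geometric lengths of stay, quarterly-style reassessments,
  optional blanked fields) that exercise the census pipeline end to end.

Default levels emulate a mid-size facility: weekly/biweekly oscillations,
per-group volumes from a handful to a few tens of residents, a low-volume
group with many zero days, and staffing intensities of order 0.1-1.5 RN/LPN
hours and ~2.5 aide hours per resident-day.  The staff-time table shipped
here is synthetic — a stand-in with realistic magnitudes, not a published
payment-model schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.special import expit

from .census import (
    Assessment,
    DEFAULT_GROUPS,
    ResidentRecord,
    StaffTimeTable,
)
from .conjugate import sample_ztp

__all__ = [
    "PathSpec",
    "SharedFactor",
    "SyntheticScenario",
    "default_staff_table",
    "shared_factor_scenario",
    "simulate_series",
    "simulate_residents",
]

DEFAULT_CAREGIVERS = ("RN", "LPN", "CNA")


@dataclass(frozen=True)
class PathSpec:
    """Deterministic skeleton of a latent path: level + trend + sinusoid."""

    base: float
    trend: float = 0.0  # per-day linear drift
    amplitude: float = 0.0
    period: float = 7.0  # days
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")

    def values(self, n_days: int) -> np.ndarray:
        t = np.arange(n_days, dtype=float)
        return (
            self.base
            + self.trend * t
            + self.amplitude * np.sin(2.0 * np.pi * t / self.period + self.phase)
        )


@dataclass(frozen=True)
class SharedFactor:
    """Common factor loading on chosen groups' log intensity.

    A sinusoid plus a stationary AR(1) noise component (``ar_coef`` = 1
    degenerates to a random walk).  The AR part is what creates day-to-day
    *change* correlation between loaded groups; a smooth sinusoid alone
    moves too slowly to show up against Poisson noise in first differences.
    """

    loadings: dict[str, float]
    amplitude: float = 0.5
    period: float = 14.0
    noise_sd: float = 0.1
    ar_coef: float = 0.8

    def values(self, n_days: int, rng: np.random.Generator) -> np.ndarray:
        t = np.arange(n_days, dtype=float)
        path = self.amplitude * np.sin(2.0 * np.pi * t / self.period)
        if self.noise_sd > 0:
            innov = rng.normal(0.0, self.noise_sd, size=n_days)
            ar = np.empty(n_days)
            prev = 0.0
            for i in range(n_days):
                prev = self.ar_coef * prev + innov[i]
                ar[i] = prev
            path = path + ar
        return path


def default_staff_table(
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    caregivers: tuple[str, ...] = DEFAULT_CAREGIVERS,
) -> StaffTimeTable:
    """Synthetic hours-per-resident-day table (stand-in staffing schedule).

    Magnitudes follow facility-level staffing intensity: licensed-nurse time
    of order 0.1-1.5 h per resident-day, aide time of order 2-3 h.
    """
    base = {
        "RN": {"ESS": 1.4, "SCH": 1.1, "SCL": 0.8, "CCX": 0.9, "BSS": 0.4, "RPF": 0.3},
        "LPN": {"ESS": 1.5, "SCH": 1.2, "SCL": 1.0, "CCX": 1.0, "BSS": 0.6, "RPF": 0.5},
        "CNA": {"ESS": 3.0, "SCH": 2.8, "SCL": 2.5, "CCX": 2.4, "BSS": 2.2, "RPF": 2.0},
    }
    rows = {}
    for r in caregivers:
        rows[r] = {g: base.get(r, {}).get(g, 1.0) for g in groups}
    return StaffTimeTable(pd.DataFrame.from_dict(rows, orient="index")[list(groups)])


def _default_occupancy_paths(groups) -> dict[str, PathSpec]:
    # high-volume groups essentially always occupied; BSS-like low-volume
    # groups sit near the gate and produce the excess zeros
    presets = {
        "ESS": PathSpec(2.0, 0.0, 0.3, 14.0),
        "SCH": PathSpec(3.0, 0.0, 0.3, 7.0),
        "SCL": PathSpec(3.0, 0.0, 0.3, 14.0),
        "CCX": PathSpec(3.5, 0.0, 0.3, 7.0),
        "BSS": PathSpec(0.0, 0.0, 0.5, 14.0),
        "RPF": PathSpec(3.5, 0.0, 0.3, 7.0),
    }
    return {g: presets.get(g, PathSpec(2.0, 0.0, 0.3, 7.0)) for g in groups}


def _default_intensity_paths(groups) -> dict[str, PathSpec]:
    # log-intensity levels giving volumes of ~2 (BSS) to ~25 (RPF) residents
    presets = {
        "ESS": PathSpec(1.1, 0.0, 0.15, 14.0),
        "SCH": PathSpec(2.2, 0.0, 0.15, 7.0),
        "SCL": PathSpec(2.0, 0.0, 0.15, 14.0),
        "CCX": PathSpec(2.5, 0.0, 0.15, 7.0),
        "BSS": PathSpec(0.7, 0.0, 0.2, 14.0),
        "RPF": PathSpec(3.0, 0.0, 0.15, 7.0),
    }
    return {g: presets.get(g, PathSpec(1.5, 0.0, 0.15, 7.0)) for g in groups}


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for the direct-series generator."""

    n_days: int = 365
    groups: tuple[str, ...] = DEFAULT_GROUPS
    caregiver_types: tuple[str, ...] = DEFAULT_CAREGIVERS
    occupancy_logit_path: dict[str, PathSpec] | None = None
    intensity_log_path: dict[str, PathSpec] | None = None
    shared_factor: SharedFactor | None = None
    state_noise_sd: float = 0.02
    staff_table: StaffTimeTable | None = None
    lognoise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.state_noise_sd < 0 or self.lognoise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.occupancy_logit_path is None:
            object.__setattr__(
                self, "occupancy_logit_path", _default_occupancy_paths(self.groups)
            )
        if self.intensity_log_path is None:
            object.__setattr__(
                self, "intensity_log_path", _default_intensity_paths(self.groups)
            )
        if self.staff_table is None:
            object.__setattr__(
                self,
                "staff_table",
                default_staff_table(self.groups, self.caregiver_types),
            )


def shared_factor_scenario(seed: int = 0, n_days: int = 365) -> SyntheticScenario:
    """Two high-volume groups driven by a strong common factor.

    The factor is a biweekly sinusoid plus a persistent AR(1) component with
    substantial daily movement, loading on both groups' log intensity.
    Day-to-day *changes* of the two count series are then strongly
    positively correlated — the signal the shared-information variant
    exploits.
    """
    groups = ("SCH", "RPF")
    return SyntheticScenario(
        n_days=n_days,
        groups=groups,
        occupancy_logit_path={g: PathSpec(4.0) for g in groups},
        intensity_log_path={
            "SCH": PathSpec(3.0, 0.0, 0.0, 14.0),
            "RPF": PathSpec(3.2, 0.0, 0.0, 14.0),
        },
        shared_factor=SharedFactor(
            {"SCH": 1.0, "RPF": 1.0},
            amplitude=0.4, period=14.0, noise_sd=0.3, ar_coef=0.8,
        ),
        state_noise_sd=0.0,
        seed=seed,
    )


def simulate_series(
    sc: SyntheticScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw daily counts and staff hours from the generative model.

    Returns ``(counts, hours, truth)``: wide DataFrames (day rows, group /
    caregiver-type columns) and the latent truth ``{"p": DataFrame,
    "eta": DataFrame}``.  Fully reproducible from ``sc.seed``.
    """
    rng = np.random.default_rng(sc.seed)
    n = sc.n_days
    factor = (
        sc.shared_factor.values(n, rng) if sc.shared_factor is not None else None
    )
    p_cols, eta_cols, z_cols = {}, {}, {}
    for g in sc.groups:
        logit_p = sc.occupancy_logit_path[g].values(n)
        log_eta = sc.intensity_log_path[g].values(n)
        if sc.state_noise_sd > 0:
            logit_p = logit_p + np.cumsum(rng.normal(0, sc.state_noise_sd, n))
            log_eta = log_eta + np.cumsum(rng.normal(0, sc.state_noise_sd, n))
        if factor is not None:
            log_eta = log_eta + sc.shared_factor.loadings.get(g, 0.0) * factor
        p = expit(logit_p)
        eta = np.exp(log_eta)
        x = rng.uniform(size=n) < p
        z = np.zeros(n, dtype=np.int64)
        if x.any():
            z[x] = sample_ztp(eta[x], rng)
        p_cols[g], eta_cols[g], z_cols[g] = p, eta, z

    counts = pd.DataFrame(z_cols, columns=list(sc.groups))
    lam = sc.staff_table.hours.loc[list(sc.caregiver_types), list(sc.groups)]
    hours_clean = counts.to_numpy() @ lam.to_numpy().T  # days x caregivers
    if sc.lognoise_sd > 0:
        noise = np.exp(rng.normal(0.0, sc.lognoise_sd, size=hours_clean.shape))
        hours_vals = hours_clean * noise
    else:
        hours_vals = hours_clean
    hours = pd.DataFrame(hours_vals, columns=list(sc.caregiver_types))
    truth = {
        "p": pd.DataFrame(p_cols, columns=list(sc.groups)),
        "eta": pd.DataFrame(eta_cols, columns=list(sc.groups)),
    }
    return counts, hours, truth


def simulate_residents(
    sc: SyntheticScenario,
    admission_rate_path: np.ndarray | float = 0.6,
    los_mean_days: float = 30.0,
    group_mix: np.ndarray | None = None,
    assessment_period_days: int = 92,
    transition_prob: float = 0.15,
    blank_fraction: float = 0.0,
    start: date = date(2017, 1, 1),
) -> list[ResidentRecord]:
    """Emit resident-level records exercising the census pipeline.

    Daily admissions are Poisson with the given rate (scalar or per-day
    path); length of stay is geometric with mean ``los_mean_days``; the
    admission group follows ``group_mix``; reassessments happen every
    ``assessment_period_days`` with probability ``transition_prob`` of moving
    to a uniformly chosen other group.  ``blank_fraction`` of residents get
    their discharge date blanked and the same fraction of reassessments get
    their group blanked, to exercise cleaning and imputation.
    """
    rng = np.random.default_rng(sc.seed + 1)
    n = sc.n_days
    rates = np.broadcast_to(np.asarray(admission_rate_path, dtype=float), (n,))
    if np.any(rates < 0):
        raise ValueError("admission rates must be >= 0")
    groups = list(sc.groups)
    if group_mix is None:
        group_mix = np.full(len(groups), 1.0 / len(groups))
    group_mix = np.asarray(group_mix, dtype=float)
    if abs(group_mix.sum() - 1.0) > 1e-9 or np.any(group_mix < 0):
        raise ValueError("group_mix must be a probability vector")
    if los_mean_days < 1:
        raise ValueError("los_mean_days must be >= 1")

    records: list[ResidentRecord] = []
    rid = 0
    for day_idx in range(n):
        for _ in range(rng.poisson(rates[day_idx])):
            rid += 1
            admit = start + timedelta(days=day_idx)
            # geometric LOS with mean los_mean_days, support >= 1
            los = int(rng.geometric(1.0 / los_mean_days))
            discharge = admit + timedelta(days=los)
            g = groups[rng.choice(len(groups), p=group_mix)]
            assessments = [Assessment(admit, "admission", g)]
            k = assessment_period_days
            while k < los:
                if rng.uniform() < transition_prob:
                    others = [x for x in groups if x != g]
                    g = others[rng.integers(len(others))]
                grp: str | None = g
                if blank_fraction > 0 and rng.uniform() < blank_fraction:
                    grp = None
                assessments.append(
                    Assessment(admit + timedelta(days=k), "quarterly", grp)
                )
                k += assessment_period_days
            disc: date | None = discharge
            if blank_fraction > 0 and rng.uniform() < blank_fraction:
                disc = None
            records.append(
                ResidentRecord(
                    resident_id=f"R{rid:05d}",
                    admission_date=admit,
                    discharge_date=disc,
                    assessments=tuple(assessments),
                )
            )
    return records
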
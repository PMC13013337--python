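"""Resident-record pipeline: assessments -> daily group census -> staff hours.

Resident-level assessment extracts (admission/discharge dates plus dated
acuity assessments) are cleaned, missing discharges are resolved, and each
resident is counted in exactly one acuity group per in-facility day.  Daily
group counts are then converted to caregiver-type staff hours through a
user-supplied hours-per-resident-day table (the payment-model staffing
specification).

Conventions: the stay interval is half-open [admission, discharge) so a
transferred or readmitted resident is never double counted; a resident's
group on a day is the most recent assessment at or before that day (the
first assessment is back-filled for earlier in-stay days).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "ASSESSMENT_TYPES",
    "DEFAULT_GROUPS",
    "Assessment",
    "ResidentRecord",
    "StaffTimeTable",
    "CountSeries",
    "StaffTimeSeries",
    "clean_records",
    "resolve_discharge",
    "build_daily_census",
    "aggregate_staff_time",
]

logger = logging.getLogger(__name__)

ASSESSMENT_TYPES = (
    "admission",
    "annual",
    "quarterly",
    "significant_change",
    "death_in_facility",
    "discharge",
)

# the six non-rehab acuity categories: extensive care, special care high/low,
# clinically complex, behavioral symptoms, reduced physical function
DEFAULT_GROUPS = ("ESS", "SCH", "SCL", "CCX", "BSS", "RPF")

# days until the next expected quarterly assessment; used to carry forward a
# stay whose discharge date is missing
QUARTERLY_CYCLE_DAYS = 92


@dataclass(frozen=True)
class Assessment:
    date: date
    type_code: str
    group: str | None

    def __post_init__(self) -> None:
        if self.type_code not in ASSESSMENT_TYPES:
            raise ValueError(
                f"unknown assessment type {self.type_code!r}; expected one of {ASSESSMENT_TYPES}"
            )


@dataclass(frozen=True)
class ResidentRecord:
    """One resident's stay and dated acuity-assessment history."""

    resident_id: str
    admission_date: date
    discharge_date: date | None = None
    assessments: tuple[Assessment, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "assessments", tuple(self.assessments))


@dataclass(frozen=True)
class CountSeries:
    """Gapless daily counts for one acuity group."""

    group: str
    dates: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.dates) != counts.size:
            raise ValueError("dates and counts lengths differ")
        if counts.size and np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.size > 1 and not (np.diff(self.dates.values) == np.timedelta64(1, "D")).all():
            raise ValueError("dates must be consecutive days")
        object.__setattr__(self, "counts", counts)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.dates, name=self.group)


@dataclass(frozen=True)
class StaffTimeSeries:
    """Daily facility-wide hours for one caregiver type."""

    caregiver_type: str
    dates: pd.DatetimeIndex
    hours: np.ndarray

    def __post_init__(self) -> None:
        hours = np.asarray(self.hours, dtype=float)
        if len(self.dates) != hours.size:
            raise ValueError("dates and hours lengths differ")
        object.__setattr__(self, "hours", hours)

    def to_series(self) -> pd.Series:
        return pd.Series(self.hours, index=self.dates, name=self.caregiver_type)


@dataclass(frozen=True)
class StaffTimeTable:
    """Hours per resident-day, caregiver type x acuity group (lambda_{r,g})."""

    hours: pd.DataFrame  # index: caregiver_type, columns: group

    def __post_init__(self) -> None:
        df = self.hours.astype(float)
        if (df.to_numpy() < 0).any() or not np.isfinite(df.to_numpy()).all():
            raise ValueError("staff-time table entries must be non-negative finite")
        object.__setattr__(self, "hours", df)

    @property
    def caregiver_types(self) -> list[str]:
        return list(self.hours.index)

    @property
    def groups(self) -> list[str]:
        return list(self.hours.columns)


def clean_records(raw: list[ResidentRecord]) -> list[ResidentRecord]:
    """Deduplicate assessments, fill missing groups, drop unusable records.

    * duplicates (same resident, date, type, group) collapse to one entry;
    * an assessment with a missing group inherits the resident's most recent
      prior group;
    * residents with no usable (grouped) assessment are dropped;
    * records with admission after discharge are rejected.
    Dropped/rejected counts are logged.  The operation is idempotent.
    """
    cleaned: list[ResidentRecord] = []
    n_dropped = n_rejected = 0
    for rec in raw:
        if rec.discharge_date is not None and rec.admission_date > rec.discharge_date:
            n_rejected += 1
            logger.warning(
                "rejecting resident %s: admission %s after discharge %s",
                rec.resident_id, rec.admission_date, rec.discharge_date,
            )
            continue
        seen: set[tuple] = set()
        assessments: list[Assessment] = []
        for a in sorted(rec.assessments, key=lambda a: (a.date, a.type_code)):
            key = (a.date, a.type_code, a.group)
            if key in seen:
                continue
            seen.add(key)
            assessments.append(a)
        # fill missing groups from the most recent prior assessed group
        filled: list[Assessment] = []
        last_group: str | None = None
        for a in assessments:
            if a.group is None and last_group is not None:
                a = replace(a, group=last_group)
            if a.group is not None:
                last_group = a.group
            filled.append(a)
        usable = [a for a in filled if a.group is not None]
        if not usable:
            n_dropped += 1
            continue
        cleaned.append(replace(rec, assessments=tuple(usable)))
    if n_dropped or n_rejected:
        logger.info(
            "clean_records: dropped %d residents without usable assessments, "
            "rejected %d with inverted stay intervals", n_dropped, n_rejected,
        )
    return cleaned


def resolve_discharge(rec: ResidentRecord, study_end: date) -> ResidentRecord:
    """Impute a missing discharge date.

    A death-in-facility assessment dates the discharge exactly; otherwise the
    stay is carried forward from the last assessment until the next expected
    quarterly assessment (92 days), capped at ``study_end``.
    """
    if rec.discharge_date is not None:
        return rec
    deaths = [a.date for a in rec.assessments if a.type_code == "death_in_facility"]
    if deaths:
        return replace(rec, discharge_date=min(deaths))
    if rec.assessments:
        last = max(a.date for a in rec.assessments)
    else:
        last = rec.admission_date
    imputed = min(last + timedelta(days=QUARTERLY_CYCLE_DAYS), study_end)
    return replace(rec, discharge_date=imputed)


def build_daily_census(
    records: list[ResidentRecord],
    span: tuple[date, date],
    groups: tuple[str, ...] | None = None,
) -> dict[str, CountSeries]:
    """Daily per-group resident counts over ``span`` (both endpoints included).

    A resident occupies their current group on every day with
    admission <= day < discharge; the current group is the most recent
    assessment at or before the day, back-filled to the first assessment for
    early in-stay days (logged).  Groups with no residents get explicit
    all-zero series.
    """
    start, end = span
    if end < start:
        raise ValueError("span end before start")
    dates = pd.date_range(start, end, freq="D")
    n_days = len(dates)
    if groups is None:
        seen = {a.group for r in records for a in r.assessments if a.group}
        groups = tuple(sorted(seen)) if seen else DEFAULT_GROUPS
    counts = {g: np.zeros(n_days, dtype=np.int64) for g in groups}

    n_backfilled = 0
    for rec in records:
        if rec.discharge_date is None:
            raise ValueError(
                f"resident {rec.resident_id} has unresolved discharge; "
                "run resolve_discharge first"
            )
        if not rec.assessments:
            continue
        ass = sorted(rec.assessments, key=lambda a: a.date)
        stay_start = max(rec.admission_date, start)
        stay_stop = min(rec.discharge_date, end + timedelta(days=1))  # exclusive
        if stay_start >= stay_stop:
            continue
        if stay_start < ass[0].date:
            n_backfilled += 1
        # change-points: group is a step function of the assessment dates
        change_dates = [a.date for a in ass]
        change_groups = [a.group for a in ass]
        day = stay_start
        idx = int((pd.Timestamp(stay_start) - dates[0]).days)
        # pointer into assessments: most recent at or before `day`
        j = 0
        while j + 1 < len(change_dates) and change_dates[j + 1] <= day:
            j += 1
        while day < stay_stop:
            while j + 1 < len(change_dates) and change_dates[j + 1] <= day:
                j += 1
            g = change_groups[j] if change_dates[j] <= day else change_groups[0]
            if g in counts:
                counts[g][idx] += 1
            day += timedelta(days=1)
            idx += 1
    if n_backfilled:
        logger.info(
            "build_daily_census: back-filled first-assessment group for %d residents",
            n_backfilled,
        )
    return {g: CountSeries(g, dates, counts[g]) for g in groups}


def aggregate_staff_time(
    census: dict[str, CountSeries], table: StaffTimeTable
) -> dict[str, StaffTimeSeries]:
    """Caregiver-type hours d_{r,t} = sum_g lambda_{r,g} z_{g,t}.

    Every census group must appear in the table columns.  Zero-total days are
    emitted as 0.0 and logged (the lognormal model skips them).
    """
    groups = list(census)
    missing = [g for g in groups if g not in table.hours.columns]
    if missing:
        raise KeyError(f"groups {missing} missing from the staff-time table")
    any_series = next(iter(census.values()))
    dates = any_series.dates
    Z = np.column_stack([census[g].counts for g in groups])  # days x groups
    out: dict[str, StaffTimeSeries] = {}
    for r in table.caregiver_types:
        lam = table.hours.loc[r, groups].to_numpy(dtype=float)
        d = Z @ lam
        n_zero = int((d == 0).sum())
        if n_zero:
            logger.info("aggregate_staff_time: %s has %d zero-total days", r, n_zero)
        out[r] = StaffTimeSeries(r, dates, d)
    return out
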
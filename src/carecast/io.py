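"""CSV / JSON schemas shared by the library, the CLI and the examples.

Long-format CSVs (all dates ISO-8601):

* counts:      date, group, count
* staff time:  date, caregiver_type, hours
* staff table: caregiver_type, group, hours_per_resident_day
* residents:   resident_id, admission_date, discharge_date,
               assessment_date, assessment_type, acuity_group
               (one row per assessment; stay fields repeated per row)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .census import (
    Assessment,
    CountSeries,
    ResidentRecord,
    StaffTimeSeries,
    StaffTimeTable,
)
from .forecast import ForecastDistribution

__all__ = [
    "read_count_csv",
    "write_count_csv",
    "read_staff_csv",
    "write_staff_csv",
    "read_staff_table_csv",
    "write_staff_table_csv",
    "read_residents_csv",
    "write_residents_csv",
    "write_forecast_json",
    "read_forecast_points",
    "write_filter_trace_json",
]


def write_filter_trace_json(trace: list[dict], path) -> None:
    """Per-day filtered-state trace (predictor moments + conjugate params)."""
    Path(path).write_text(json.dumps(trace, indent=1))


def read_count_csv(path) -> pd.DataFrame:
    """Long count CSV -> wide frame (DatetimeIndex rows, group columns)."""
    df = pd.read_csv(path, parse_dates=["date"])
    wide = df.pivot(index="date", columns="group", values="count").sort_index()
    if wide.isna().any().any():
        raise ValueError(f"{path}: missing (date, group) combinations")
    return wide.astype(np.int64)


def write_count_csv(census: dict[str, CountSeries] | pd.DataFrame, path) -> None:
    if isinstance(census, dict):
        wide = pd.concat({g: s.to_series() for g, s in census.items()}, axis=1)
    else:
        wide = census
    long = wide.rename_axis("date").reset_index().melt(
        id_vars="date", var_name="group", value_name="count"
    )
    long.sort_values(["date", "group"]).to_csv(path, index=False, date_format="%Y-%m-%d")


def read_staff_csv(path) -> pd.DataFrame:
    """Long staff-time CSV -> wide frame (rows days, caregiver-type columns)."""
    df = pd.read_csv(path, parse_dates=["date"])
    wide = df.pivot(index="date", columns="caregiver_type", values="hours").sort_index()
    if wide.isna().any().any():
        raise ValueError(f"{path}: missing (date, caregiver_type) combinations")
    return wide.astype(float)


def write_staff_csv(staff: dict[str, StaffTimeSeries] | pd.DataFrame, path) -> None:
    if isinstance(staff, dict):
        wide = pd.concat({r: s.to_series() for r, s in staff.items()}, axis=1)
    else:
        wide = staff
    long = wide.rename_axis("date").reset_index().melt(
        id_vars="date", var_name="caregiver_type", value_name="hours"
    )
    long.sort_values(["date", "caregiver_type"]).to_csv(
        path, index=False, date_format="%Y-%m-%d"
    )


def read_staff_table_csv(path) -> StaffTimeTable:
    df = pd.read_csv(path)
    wide = df.pivot(
        index="caregiver_type", columns="group", values="hours_per_resident_day"
    )
    return StaffTimeTable(wide)


def write_staff_table_csv(table: StaffTimeTable, path) -> None:
    long = (
        table.hours.rename_axis("caregiver_type")
        .reset_index()
        .melt(id_vars="caregiver_type", var_name="group",
              value_name="hours_per_resident_day")
    )
    long.to_csv(path, index=False)


def read_residents_csv(path) -> list[ResidentRecord]:
    df = pd.read_csv(
        path,
        parse_dates=["admission_date", "discharge_date", "assessment_date"],
    )
    records: list[ResidentRecord] = []
    for rid, sub in df.groupby("resident_id", sort=True):
        admission = sub["admission_date"].iloc[0].date()
        disc = sub["discharge_date"].iloc[0]
        discharge = None if pd.isna(disc) else disc.date()
        assessments = []
        for _, row in sub.iterrows():
            group = row.get("acuity_group")
            assessments.append(
                Assessment(
                    row["assessment_date"].date(),
                    row["assessment_type"],
                    None if pd.isna(group) else str(group),
                )
            )
        records.append(
            ResidentRecord(str(rid), admission, discharge, tuple(assessments))
        )
    return records


def write_residents_csv(records: list[ResidentRecord], path) -> None:
    rows = []
    for rec in records:
        for a in rec.assessments:
            rows.append(
                {
                    "resident_id": rec.resident_id,
                    "admission_date": rec.admission_date.isoformat(),
                    "discharge_date": (
                        rec.discharge_date.isoformat() if rec.discharge_date else ""
                    ),
                    "assessment_date": a.date.isoformat(),
                    "assessment_type": a.type_code,
                    "acuity_group": a.group or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_forecast_json(
    forecasts: dict[str, list[ForecastDistribution]],
    path,
    levels: tuple[float, ...] = (0.5, 0.9),
) -> None:
    """Per series, per origin, per day: point forecast plus central intervals."""
    payload = {}
    for label, fcs in forecasts.items():
        payload[label] = []
        for fc in fcs:
            entry = {
                "origin_day": int(fc.origin_day),
                "point": np.asarray(fc.point, dtype=float).tolist(),
            }
            for level in levels:
                lo, hi = fc.interval(level)
                entry[f"interval_{int(level * 100)}"] = [lo.tolist(), hi.tolist()]
            payload[label].append(entry)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_forecast_points(path) -> dict[str, np.ndarray]:
    """Concatenated point forecasts per series from a forecast JSON file."""
    payload = json.loads(Path(path).read_text())
    return {
        label: np.concatenate([np.asarray(e["point"], dtype=float) for e in entries])
        for label, entries in payload.items()
    }
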
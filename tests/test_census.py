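"""Census pipeline: cleaning, discharge resolution, daily counts, staffing."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from carecast.census import (
    Assessment,
    ResidentRecord,
    StaffTimeTable,
    aggregate_staff_time,
    build_daily_census,
    clean_records,
    resolve_discharge,
)


def rec(rid, admit, discharge=None, assessments=()):
    return ResidentRecord(rid, admit, discharge, tuple(assessments))


class TestCleanRecords:
    def test_duplicate_assessments_collapse(self):
        r = rec(
            "R1", date(2017, 1, 1), date(2017, 6, 1),
            [
                Assessment(date(2017, 2, 1), "quarterly", "SCH"),
                Assessment(date(2017, 2, 1), "quarterly", "SCH"),
            ],
        )
        out = clean_records([r])
        assert len(out[0].assessments) == 1

    def test_missing_group_filled_from_most_recent(self):
        r = rec(
            "R1", date(2017, 1, 1), date(2017, 6, 1),
            [
                Assessment(date(2017, 1, 30), "admission", "SCH"),
                Assessment(date(2017, 3, 1), "quarterly", None),
            ],
        )
        out = clean_records([r])
        assert out[0].assessments[1].group == "SCH"

    def test_resident_without_usable_assessment_dropped(self):
        r = rec("R1", date(2017, 1, 1), None,
                [Assessment(date(2017, 1, 1), "admission", None)])
        assert clean_records([r]) == []

    def test_inverted_interval_rejected(self):
        r = rec("R1", date(2017, 5, 1), date(2017, 2, 1),
                [Assessment(date(2017, 5, 1), "admission", "ESS")])
        assert clean_records([r]) == []

    def test_empty_input(self):
        assert clean_records([]) == []

    def test_idempotent(self):
        rng_records = [
            rec(
                f"R{i}", date(2017, 1, 1 + i), date(2017, 6, 1),
                [
                    Assessment(date(2017, 1, 1 + i), "admission", "CCX"),
                    Assessment(date(2017, 1, 1 + i), "admission", "CCX"),
                    Assessment(date(2017, 4, 1), "quarterly", None),
                ],
            )
            for i in range(4)
        ]
        once = clean_records(rng_records)
        twice = clean_records(once)
        assert once == twice


class TestResolveDischarge:
    def test_death_in_facility_dates_discharge(self):
        r = rec("R1", date(2017, 1, 1), None,
                [
                    Assessment(date(2017, 1, 1), "admission", "ESS"),
                    Assessment(date(2017, 6, 1), "death_in_facility", "ESS"),
                ])
        assert resolve_discharge(r, date(2017, 12, 31)).discharge_date == date(2017, 6, 1)

    def test_carry_forward_capped_at_study_end(self):
        r = rec("R1", date(2017, 9, 1), None,
                [Assessment(date(2017, 10, 1), "quarterly", "SCH")])
        out = resolve_discharge(r, date(2017, 12, 31))
        assert out.discharge_date == date(2017, 12, 31)

    def test_carry_forward_quarterly_cycle(self):
        r = rec("R1", date(2017, 1, 1), None,
                [Assessment(date(2017, 1, 1), "admission", "SCH")])
        out = resolve_discharge(r, date(2017, 12, 31))
        assert out.discharge_date == date(2017, 1, 1) + timedelta(days=92)

    def test_present_discharge_unchanged(self):
        r = rec("R1", date(2017, 1, 1), date(2017, 3, 1),
                [Assessment(date(2017, 1, 1), "admission", "SCH")])
        assert resolve_discharge(r, date(2017, 12, 31)) is r


class TestBuildDailyCensus:
    SPAN = (date(2017, 1, 1), date(2017, 1, 10))

    def test_half_open_interval(self):
        r = rec("R1", date(2017, 1, 3), date(2017, 1, 5),
                [Assessment(date(2017, 1, 3), "admission", "ESS")])
        census = build_daily_census([r], self.SPAN)
        np.testing.assert_array_equal(
            census["ESS"].counts, [0, 0, 1, 1, 0, 0, 0, 0, 0, 0]
        )

    def test_group_change_is_step_function(self):
        r = rec("R1", date(2017, 1, 1), date(2017, 1, 11),
                [
                    Assessment(date(2017, 1, 1), "admission", "SCH"),
                    Assessment(date(2017, 1, 6), "significant_change", "CCX"),
                ])
        census = build_daily_census([r], self.SPAN, groups=("SCH", "CCX"))
        np.testing.assert_array_equal(census["SCH"].counts[:6], [1] * 5 + [0])
        np.testing.assert_array_equal(census["CCX"].counts[4:7], [0, 1, 1])

    def test_backfill_before_first_assessment(self):
        r = rec("R1", date(2017, 1, 1), date(2017, 1, 4),
                [Assessment(date(2017, 1, 3), "admission", "BSS")])
        census = build_daily_census([r], self.SPAN)
        np.testing.assert_array_equal(census["BSS"].counts[:4], [1, 1, 1, 0])

    def test_empty_group_gets_explicit_zeros(self):
        r = rec("R1", date(2017, 1, 1), date(2017, 1, 3),
                [Assessment(date(2017, 1, 1), "admission", "ESS")])
        census = build_daily_census([r], self.SPAN, groups=("ESS", "BSS"))
        assert (census["BSS"].counts == 0).all()
        assert len(census["BSS"].counts) == 10

    def test_ten_resident_fixture_matches_brute_force(self):
        """Hand-written 10-resident roster vs a per-resident day scan."""
        groups = ("ESS", "SCH", "CCX")
        records = []
        for i in range(10):
            admit = date(2017, 1, 1 + i)
            discharge = admit + timedelta(days=3 + (i % 5))
            g0 = groups[i % 3]
            assessments = [Assessment(admit, "admission", g0)]
            if i % 2 == 0:
                assessments.append(
                    Assessment(admit + timedelta(days=2), "significant_change",
                               groups[(i + 1) % 3])
                )
            records.append(rec(f"R{i}", admit, discharge, assessments))
        span = (date(2017, 1, 1), date(2017, 1, 20))
        census = build_daily_census(records, span, groups=groups)

        days = pd.date_range(*span, freq="D")
        for gi, g in enumerate(groups):
            brute = np.zeros(len(days), dtype=int)
            for di, d in enumerate(days):
                d = d.date()
                for r in records:
                    if not (r.admission_date <= d < r.discharge_date):
                        continue
                    current = None
                    for a in sorted(r.assessments, key=lambda a: a.date):
                        if a.date <= d:
                            current = a.group
                    if current is None:
                        current = sorted(r.assessments, key=lambda a: a.date)[0].group
                    if current == g:
                        brute[di] += 1
            np.testing.assert_array_equal(census[g].counts, brute)

    def test_unresolved_discharge_rejected(self):
        r = rec("R1", date(2017, 1, 1), None,
                [Assessment(date(2017, 1, 1), "admission", "ESS")])
        with pytest.raises(ValueError, match="unresolved"):
            build_daily_census([r], self.SPAN)


class TestAggregateStaffTime:
    @staticmethod
    def census_fixture():
        dates = pd.date_range("2017-01-01", periods=3, freq="D")
        from carecast.census import CountSeries
        return {
            "A": CountSeries("A", dates, [2, 0, 4]),
            "B": CountSeries("B", dates, [3, 0, 1]),
        }

    def test_hand_computed_hours(self):
        table = StaffTimeTable(pd.DataFrame({"A": [0.5], "B": [1.0]}, index=["RN"]))
        out = aggregate_staff_time(self.census_fixture(), table)
        np.testing.assert_array_equal(out["RN"].hours, [4.0, 0.0, 3.0])

    def test_homogeneity(self):
        t1 = StaffTimeTable(pd.DataFrame({"A": [0.5], "B": [1.0]}, index=["RN"]))
        t2 = StaffTimeTable(pd.DataFrame({"A": [1.0], "B": [2.0]}, index=["RN"]))
        c = self.census_fixture()
        np.testing.assert_allclose(
            2.0 * aggregate_staff_time(c, t1)["RN"].hours,
            aggregate_staff_time(c, t2)["RN"].hours,
        )

    def test_bit_exact_rational_arithmetic(self):
        table = StaffTimeTable(
            pd.DataFrame({"A": [0.25], "B": [1.5]}, index=["CNA"])
        )
        out = aggregate_staff_time(self.census_fixture(), table)
        assert out["CNA"].hours[0] == 2 * 0.25 + 3 * 1.5  # exact float arithmetic

    def test_unknown_group_raises(self):
        table = StaffTimeTable(pd.DataFrame({"A": [0.5]}, index=["RN"]))
        with pytest.raises(KeyError, match="missing"):
            aggregate_staff_time(self.census_fixture(), table)
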
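import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortmsm.cohort import (
    PatientRecord,
    StructuralError,
    apply_itt_carry_forward,
    check_eligibility,
    expand_person_months,
    locf_and_lag_covariates,
    person_month_table,
    read_cohort_csv,
    write_cohort_csv,
)
from conftest import make_record


# ---------------------------------------------------------------------------
# eligibility


def _raw_record(art_start_month, cd4_series, **kw):
    rec = make_record(**kw)
    rec.art_start_month = art_start_month
    rec.cd4_series = cd4_series
    return rec


class TestEligibility:
    def test_eligible_at_opening(self):
        # 20 months on ART and CD4 350 at study start
        rec = _raw_record(-20, [(0, 350.0)])
        res = check_eligibility(rec, study_start=0, study_end=40)
        assert res.eligible and res.entry_month == 0

    def test_first_qualifying_visit(self):
        # CD4 150 at opening, 250 measured 4 months later
        rec = _raw_record(-30, [(0, 150.0), (4, 250.0)])
        res = check_eligibility(rec, 0, 40)
        assert res.eligible and res.entry_month == 4

    def test_art_duration_reached_after_study_end(self):
        rec = _raw_record(30, [(0, 350.0), (45, 400.0)])
        res = check_eligibility(rec, 0, 40)
        assert not res.eligible

    def test_missing_art_start_reason_code(self):
        rec = _raw_record(None, [(0, 350.0)])
        res = check_eligibility(rec, 0, 40)
        assert not res.eligible and res.reason == "missing_art_start"

    def test_art_duration_gates_entry(self):
        # 10 months on ART at opening -> eligible at month 8
        rec = _raw_record(-10, [(0, 500.0)])
        res = check_eligibility(rec, 0, 40)
        assert res.eligible and res.entry_month == 8

    def test_cd4_never_above_threshold(self):
        rec = _raw_record(-30, [(0, 150.0)])
        res = check_eligibility(rec, 0, 40)
        assert not res.eligible and res.reason == "cd4_never_above_threshold"


# ---------------------------------------------------------------------------
# person-month expansion


class TestExpansion:
    def test_event_at_t5(self):
        rec = make_record(follow_up=10, death_ltf=5)
        rows = expand_person_months(rec, "death_ltf")
        assert len(rows) == 6
        assert [r.y for r in rows] == [False] * 5 + [True]
        assert [r.t for r in rows] == list(range(6))

    def test_admin_censor_at_t3(self):
        rec = make_record(follow_up=3)
        rows = expand_person_months(rec, "death_ltf")
        assert len(rows) == 4
        assert not any(r.y for r in rows)
        assert rows[-1].censored and not rows[-1].censor_ltf

    def test_toy_cohort_total_rows(self, toy_cohort):
        # follow-ups 5, 3, 8 -> (5+1) + (3+1) + (8+1) = 19 rows
        total = sum(len(expand_person_months(r, "death_ltf")) for r in toy_cohort)
        assert total == 19

    def test_event_before_entry_raises(self):
        rec = make_record(follow_up=10)
        rec.event_month_death_ltf = rec.entry_month - 2
        with pytest.raises(StructuralError):
            expand_person_months(rec, "death_ltf")

    def test_rebound_requires_entry_suppression(self):
        rec = make_record(follow_up=5, vl_suppressed_entry=False)
        with pytest.raises(ValueError, match="suppressed at study entry"):
            expand_person_months(rec, "rebound")

    def test_rebound_ltf_censoring(self):
        # LTF at month 4 censors the rebound analysis at month 4
        rec = make_record(follow_up=10, death_ltf=4)
        rows = expand_person_months(rec, "rebound")
        assert len(rows) == 5
        assert rows[-1].censored and rows[-1].censor_ltf
        assert not any(r.y for r in rows)

    def test_rebound_event(self):
        rec = make_record(follow_up=10, rebound=6)
        rows = expand_person_months(rec, "rebound")
        assert len(rows) == 7 and rows[-1].y


class TestIttCarryForward:
    def test_pattern_club_at_8(self):
        rec = make_record(follow_up=12, club_entry=8)
        rows = expand_person_months(rec, "death_ltf")
        assert "".join("T" if r.in_club else "F" for r in rows) == "FFFFFFFF" + "TTTTT"

    def test_no_club_all_false(self):
        rows = expand_person_months(make_record(follow_up=12), "death_ltf")
        assert not any(r.in_club for r in rows)

    def test_club_at_zero_all_true(self):
        rows = expand_person_months(make_record(follow_up=12, club_entry=0), "death_ltf")
        assert all(r.in_club for r in rows)

    @given(club=st.one_of(st.none(), st.integers(0, 12)), n=st.integers(1, 13))
    @settings(max_examples=50, deadline=None)
    def test_monotone_never_reverts(self, club, n):
        rows = expand_person_months(make_record(follow_up=12), "death_ltf")[:n]
        rows = apply_itt_carry_forward(rows, club, entry_month=0)
        flags = [r.in_club for r in rows]
        assert flags == sorted(flags)  # False..False True..True
        if club is not None and club < n:
            assert flags[club] and not any(flags[:club])


class TestLocfAndLag:
    def test_locf_between_measurements(self):
        rec = make_record(follow_up=10, cd4_series=[(0, 300.0), (7, 400.0)])
        rows = expand_person_months(rec, "death_ltf")
        by_t = {r.t: r for r in rows}
        assert by_t[6].cd4_current == 300.0
        assert by_t[7].cd4_current == 400.0

    def test_lag6_definition(self):
        series = [(t, 300.0 + 10 * t) for t in range(11)]
        rec = make_record(follow_up=10, cd4_series=series)
        rows = expand_person_months(rec, "death_ltf")
        by_t = {r.t: r for r in rows}
        assert by_t[10].cd4_lag6 == by_t[4].cd4_current

    def test_lag_boundary_uses_entry_value(self):
        series = [(0, 333.0)] + [(t, 400.0) for t in range(1, 6)]
        rec = make_record(follow_up=8, cd4_series=series)
        rows = expand_person_months(rec, "death_ltf")
        by_t = {r.t: r for r in rows}
        assert by_t[3].cd4_lag6 == 333.0

    def test_no_pre_entry_measurement_names_patient(self):
        rec = make_record(patient_id="px", follow_up=5, cd4_series=[(3, 300.0)])
        with pytest.raises(ValueError, match="px"):
            expand_person_months(rec, "death_ltf")

    def test_locf_and_lag_covariates_fills_rows(self):
        rec = make_record(follow_up=10)
        rows = expand_person_months(rec, "death_ltf")
        rows = locf_and_lag_covariates(
            rows, [(0, 280.0), (5, 500.0)], [(0, True), (6, False)], entry_month=0
        )
        assert rows[4].cd4_current == 280.0 and rows[5].cd4_current == 500.0
        assert rows[5].vl_suppressed and not rows[6].vl_suppressed


# ---------------------------------------------------------------------------
# invariants


class TestTableInvariants:
    def test_person_month_conservation(self, toy_cohort):
        pm = person_month_table(toy_cohort, "death_ltf")
        expected = sum(
            r.exit_month("death_ltf") - r.entry_month + 1 for r in toy_cohort
        )
        assert len(pm) == expected

    def test_person_years_match_entry_exit(self, toy_cohort):
        pm = person_month_table(toy_cohort, "death_ltf")
        for rec in toy_cohort:
            rows = (pm["patient_id"] == rec.patient_id).sum()
            span = rec.exit_month("death_ltf") - rec.entry_month
            assert abs(rows / 12.0 - span / 12.0) <= 1.0 / 12.0 + 1e-12

    def test_measurement_order_invariance(self):
        series = [(0, 300.0), (3, 350.0), (7, 250.0), (9, 500.0)]
        rec1 = make_record(follow_up=10, cd4_series=list(series))
        rec2 = make_record(follow_up=10, cd4_series=list(reversed(series)))
        pm1 = person_month_table([rec1], "death_ltf")
        pm2 = person_month_table([rec2], "death_ltf")
        pd.testing.assert_frame_equal(pm1, pm2)

    def test_no_rows_after_ltf_in_rebound(self):
        rec = make_record(follow_up=20, death_ltf=7)
        pm = person_month_table([rec], "rebound")
        assert pm["t"].max() == 7

    def test_expand_matches_table(self, toy_cohort):
        pm = person_month_table(toy_cohort, "death_ltf")
        rows = [
            r for rec in toy_cohort for r in expand_person_months(rec, "death_ltf")
        ]
        assert len(rows) == len(pm)
        assert [r.in_club for r in rows] == list(pm["in_club"])
        assert [r.cd4_current for r in rows] == list(pm["cd4_current"])

    def test_rebound_excludes_unsuppressed_patients(self):
        recs = [
            make_record("s", follow_up=5, vl_suppressed_entry=True),
            make_record("u", follow_up=5, vl_suppressed_entry=False),
        ]
        pm = person_month_table(recs, "rebound")
        assert set(pm["patient_id"]) == {"s"}

    def test_rebound_no_suppressed_raises(self):
        recs = [make_record(follow_up=5, vl_suppressed_entry=False)]
        with pytest.raises(ValueError, match="suppressed"):
            person_month_table(recs, "rebound")


class TestValidation:
    def test_rejects_underage(self):
        rec = make_record(age_entry=16.0)
        with pytest.raises(ValueError, match="age"):
            rec.validate()

    def test_rejects_low_entry_cd4(self):
        rec = make_record(cd4_entry=150.0, cd4_series=[(0, 150.0)])
        with pytest.raises(ValueError, match="cd4_entry"):
            rec.validate()

    def test_rejects_club_after_exit(self):
        rec = make_record(follow_up=5, death_ltf=3)
        rec.club_entry_month = rec.entry_month + 4
        with pytest.raises(StructuralError):
            rec.validate()

    def test_valid_record_passes(self):
        make_record(follow_up=5, club_entry=2).validate()


# ---------------------------------------------------------------------------
# CSV round trip


def test_csv_round_trip(tmp_path, toy_cohort):
    base, meas = tmp_path / "baseline.csv", tmp_path / "measurements.csv"
    write_cohort_csv(toy_cohort, base, meas)
    back = read_cohort_csv(base, meas)
    assert [r.patient_id for r in back] == [r.patient_id for r in toy_cohort]
    pm1 = person_month_table(toy_cohort, "death_ltf")
    pm2 = person_month_table(back, "death_ltf")
    pd.testing.assert_frame_equal(pm1, pm2)


def test_csv_missing_column_errors(tmp_path, toy_cohort):
    base, meas = tmp_path / "baseline.csv", tmp_path / "measurements.csv"
    write_cohort_csv(toy_cohort, base, meas)
    df = pd.read_csv(base).drop(columns=["who_stage"])
    df.to_csv(base, index=False)
    with pytest.raises(ValueError, match="who_stage"):
        read_cohort_csv(base, meas)
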
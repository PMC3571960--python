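"""Shared fixtures: hand-built patient records and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cohortmsm.cohort import PatientRecord


def make_record(
    patient_id="p0",
    entry_month=0,
    follow_up=10,
    club_entry=None,
    death_ltf=None,
    rebound=None,
    cd4_entry=350.0,
    vl_suppressed_entry=True,
    cd4_series=None,
    vl_series=None,
    **kw,
) -> PatientRecord:
    """Record with sensible defaults; event months given relative to entry."""
    entry = entry_month
    rec = PatientRecord(
        patient_id=patient_id,
        age_entry=kw.pop("age_entry", 35.0),
        gender=kw.pop("gender", "female"),
        cd4_art_start=kw.pop("cd4_art_start", 120.0),
        cd4_entry=cd4_entry,
        vl_suppressed_entry=vl_suppressed_entry,
        art_duration_entry=kw.pop("art_duration_entry", 30.0),
        who_stage=kw.pop("who_stage", "III/IV"),
        entry_month=entry,
        admin_censor_month=entry + follow_up,
        cd4_series=cd4_series if cd4_series is not None else [(entry, cd4_entry)],
        vl_series=vl_series if vl_series is not None else [(entry, vl_suppressed_entry)],
        club_entry_month=None if club_entry is None else entry + club_entry,
        event_month_death_ltf=None if death_ltf is None else entry + death_ltf,
        event_month_rebound=None if rebound is None else entry + rebound,
        art_start_month=kw.pop("art_start_month", entry - 30),
        **kw,
    )
    return rec


@pytest.fixture
def toy_cohort():
    """Three patients with follow-ups 5, 3, 8 months; one death/LTF event."""
    return [
        make_record("a", follow_up=5, death_ltf=5),
        make_record("b", follow_up=3),
        make_record("c", follow_up=8, club_entry=2),
    ]


@pytest.fixture(scope="session")
def small_confounded_cohort():
    from cohortmsm import preset, simulate_cohort

    return simulate_cohort(preset("confounded", n_patients=2000), seed=42)


@pytest.fixture(scope="session")
def small_confounded_pm(small_confounded_cohort):
    from cohortmsm import person_month_table

    return person_month_table(small_confounded_cohort, "death_ltf")


def tiny_person_months() -> pd.DataFrame:
    """Six patients, hand-written rows, for brute-force variance checks."""
    rows = [
        # pid, t, in_club, x, y
        ("p1", 0, 0, 1.2, 0), ("p1", 1, 0, 1.1, 0), ("p1", 2, 1, 0.9, 1),
        ("p2", 0, 0, -0.3, 0), ("p2", 1, 0, -0.5, 0), ("p2", 2, 0, -0.2, 0),
        ("p2", 3, 0, 0.1, 1),
        ("p3", 0, 1, 0.4, 0), ("p3", 1, 1, 0.6, 0),
        ("p4", 0, 0, 2.0, 1),
        ("p5", 0, 0, -1.0, 0), ("p5", 1, 1, -1.2, 0), ("p5", 2, 1, -0.8, 1),
        ("p6", 0, 0, 0.0, 0), ("p6", 1, 0, 0.3, 0), ("p6", 2, 0, 0.2, 0),
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "t", "in_club", "x", "y"])
    df["in_club"] = df["in_club"].astype(bool)
    df["y"] = df["y"].astype(bool)
    return df
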
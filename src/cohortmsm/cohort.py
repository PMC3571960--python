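"""Cohort data model and discrete-time person-month expansion.

Patients are represented by :class:`PatientRecord` (baseline covariates,
dated measurement series, treatment/outcome/censoring months on a common
integer calendar-month scale).  :func:`expand_person_months` turns a record
into one row per month of follow-up; :func:`person_month_table` does the
same for a whole cohort and returns a :class:`pandas.DataFrame` on which all
weighting and estimation operates.

Conventions
-----------
* Follow-up time ``t`` is months since study entry, 0-based; an event in
  month ``t`` is attributed to row ``t`` and is the patient's last row.
* Death and loss to follow-up (LTF) form a single combined endpoint
  (``outcome="death_ltf"``).  For the virologic-rebound analysis
  (``outcome="rebound"``) death/LTF acts as censoring and the analysis is
  restricted to patients suppressed at study entry.
* Once a patient joins a club they are treated as in-club for the rest of
  follow-up (intention-to-treat carry-forward).
* CD4 and viral-load status are carried forward between measurements
  (LOCF); the 6-month lag falls back to the entry value for ``t < 6``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "PersonMonthRow",
    "EligibilityResult",
    "StructuralError",
    "check_eligibility",
    "expand_person_months",
    "apply_itt_carry_forward",
    "locf_and_lag_covariates",
    "person_month_table",
    "read_cohort_csv",
    "write_cohort_csv",
    "PERSON_MONTH_COLUMNS",
]

CD4_ELIGIBILITY_THRESHOLD = 200.0
MIN_ART_MONTHS = 18
MIN_AGE = 18.0
LAG_MONTHS = 6

#: Fixed column order of the person-month table.
PERSON_MONTH_COLUMNS = [
    "patient_id",
    "t",
    "in_club",
    "cd4_current",
    "cd4_lag6",
    "vl_suppressed",
    "y",
    "censored",
    "censor_ltf",
    "age_entry",
    "female",
    "cd4_art_start",
    "cd4_entry",
    "vl_suppressed_entry",
    "art_duration_entry",
    "who_stage34",
]


class StructuralError(ValueError):
    """Raised when a record's dates are internally inconsistent."""


@dataclass
class PatientRecord:
    """One patient: baseline covariates, measurement series, event months.

    All ``*_month`` fields are integer indices on a shared calendar-month
    scale (month 0 = study opening).  ``cd4_series`` and ``vl_series`` are
    lists of ``(calendar_month, value)`` pairs.
    """

    patient_id: str
    age_entry: float
    gender: str  # "female" | "male"
    cd4_art_start: float
    cd4_entry: float
    vl_suppressed_entry: bool
    art_duration_entry: float  # months on ART at study entry
    who_stage: str  # "I/II" | "III/IV"
    entry_month: int
    admin_censor_month: int
    cd4_series: list[tuple[int, float]] = field(default_factory=list)
    vl_series: list[tuple[int, bool]] = field(default_factory=list)
    club_entry_month: int | None = None
    event_month_death_ltf: int | None = None
    event_month_rebound: int | None = None
    art_start_month: int | None = None

    def validate(self) -> None:
        if self.age_entry < MIN_AGE:
            raise ValueError(f"{self.patient_id}: age_entry {self.age_entry} < {MIN_AGE}")
        if self.art_duration_entry < MIN_ART_MONTHS:
            raise ValueError(
                f"{self.patient_id}: art_duration_entry {self.art_duration_entry} "
                f"< {MIN_ART_MONTHS}"
            )
        if self.cd4_entry <= CD4_ELIGIBILITY_THRESHOLD:
            raise ValueError(
                f"{self.patient_id}: cd4_entry {self.cd4_entry} must exceed "
                f"{CD4_ELIGIBILITY_THRESHOLD}"
            )
        if self.gender not in ("female", "male"):
            raise ValueError(f"{self.patient_id}: unknown gender {self.gender!r}")
        if self.who_stage not in ("I/II", "III/IV"):
            raise ValueError(f"{self.patient_id}: unknown who_stage {self.who_stage!r}")
        exit_month = self.exit_month("death_ltf")
        for name in ("club_entry_month", "event_month_death_ltf", "event_month_rebound"):
            m = getattr(self, name)
            if m is not None and m < self.entry_month:
                raise StructuralError(
                    f"{self.patient_id}: {name}={m} precedes entry_month={self.entry_month}"
                )
        if self.admin_censor_month < self.entry_month:
            raise StructuralError(
                f"{self.patient_id}: admin_censor_month precedes entry_month"
            )
        if self.club_entry_month is not None and self.club_entry_month > exit_month:
            raise StructuralError(
                f"{self.patient_id}: club_entry_month={self.club_entry_month} "
                f"follows exit month {exit_month}"
            )

    def exit_month(self, outcome: str) -> int:
        """Calendar month of exit for the given outcome's analysis."""
        if outcome == "death_ltf":
            candidates = [self.admin_censor_month]
            if self.event_month_death_ltf is not None:
                candidates.append(self.event_month_death_ltf)
        elif outcome == "rebound":
            candidates = [self.admin_censor_month]
            if self.event_month_death_ltf is not None:
                candidates.append(self.event_month_death_ltf)
            if self.event_month_rebound is not None:
                candidates.append(self.event_month_rebound)
        else:
            raise ValueError(f"unknown outcome {outcome!r}")
        return min(candidates)


@dataclass
class PersonMonthRow:
    """One row of the discrete-time expansion (see PERSON_MONTH_COLUMNS)."""

    patient_id: str
    t: int
    in_club: bool
    cd4_current: float
    cd4_lag6: float
    vl_suppressed: bool
    y: bool
    censored: bool
    censor_ltf: bool
    age_entry: float
    female: bool
    cd4_art_start: float
    cd4_entry: float
    vl_suppressed_entry: bool
    art_duration_entry: float
    who_stage34: bool


@dataclass
class EligibilityResult:
    eligible: bool
    entry_month: int | None
    reason: str  # "" when eligible


def check_eligibility(
    record: PatientRecord, study_start: int, study_end: int
) -> EligibilityResult:
    """First calendar month in [study_start, study_end] at which the record
    qualifies: >= 18 months on ART and latest CD4 measurement > 200.

    ART duration at month m is derived from ``art_start_month``; a record
    without one is rejected with reason ``"missing_art_start"``.
    """
    if record.art_start_month is None:
        return EligibilityResult(False, None, "missing_art_start")
    if not record.cd4_series:
        return EligibilityResult(False, None, "no_cd4_measurements")
    if record.age_entry < MIN_AGE:
        return EligibilityResult(False, None, "under_age")

    months = sorted(m for m, _ in record.cd4_series)
    earliest_art = record.art_start_month + MIN_ART_MONTHS
    for m in range(max(study_start, earliest_art), study_end + 1):
        cd4 = _latest_at(record.cd4_series, m)
        if cd4 is not None and cd4 > CD4_ELIGIBILITY_THRESHOLD:
            return EligibilityResult(True, m, "")
    if earliest_art > study_end:
        return EligibilityResult(False, None, "art_duration_after_study_end")
    return EligibilityResult(False, None, "cd4_never_above_threshold")


def _latest_at(series: Sequence[tuple[int, float]], month: int):
    """Last measured value at or before `month`, or None."""
    best_m, best_v = None, None
    for m, v in series:
        if m <= month and (best_m is None or m >= best_m):
            best_m, best_v = m, v
    return best_v


# ---------------------------------------------------------------------------
# expansion


def _expand_arrays(record: PatientRecord, outcome: str) -> dict[str, np.ndarray]:
    """Vectorized core of the person-month expansion (relative time)."""
    entry = record.entry_month
    if outcome == "rebound" and not record.vl_suppressed_entry:
        raise ValueError(
            f"{record.patient_id}: rebound analysis is restricted to patients "
            "virologically suppressed at study entry"
        )
    event_month = (
        record.event_month_death_ltf if outcome == "death_ltf" else record.event_month_rebound
    )
    if event_month is not None and event_month < entry:
        raise StructuralError(
            f"{record.patient_id}: event month {event_month} precedes entry {entry}"
        )
    exit_month = record.exit_month(outcome)
    n = exit_month - entry + 1
    t = np.arange(n)

    y = np.zeros(n, dtype=bool)
    censored = np.zeros(n, dtype=bool)
    censor_ltf = np.zeros(n, dtype=bool)
    if event_month is not None and event_month == exit_month:
        y[-1] = True
    else:
        censored[-1] = True
        if (
            outcome == "rebound"
            and record.event_month_death_ltf is not None
            and record.event_month_death_ltf == exit_month
        ):
            censor_ltf[-1] = True

    in_club = _itt_indicator(t, record.club_entry_month, entry)
    cd4_current, cd4_lag6 = _locf_lag(record.cd4_series, entry, n, record.patient_id, "CD4")
    vl_current, _ = _locf_lag(
        [(m, float(v)) for m, v in record.vl_series], entry, n, record.patient_id, "viral load"
    )

    return {
        "t": t,
        "in_club": in_club,
        "cd4_current": cd4_current,
        "cd4_lag6": cd4_lag6,
        "vl_suppressed": vl_current.astype(bool),
        "y": y,
        "censored": censored,
        "censor_ltf": censor_ltf,
    }


def _itt_indicator(t: np.ndarray, club_entry_month: int | None, entry: int) -> np.ndarray:
    if club_entry_month is None:
        return np.zeros(len(t), dtype=bool)
    return t >= (club_entry_month - entry)


def _locf_lag(
    series: Sequence[tuple[int, float]],
    entry: int,
    n: int,
    patient_id: str,
    what: str,
) -> tuple[np.ndarray, np.ndarray]:
    """LOCF values at t=0..n-1 plus the 6-month-lagged series."""
    if not series:
        raise ValueError(f"{patient_id}: no {what} measurement at or before entry")
    arr = sorted(series)
    months = np.array([m for m, _ in arr])
    values = np.array([v for _, v in arr], dtype=float)
    if months[0] > entry:
        raise ValueError(f"{patient_id}: no {what} measurement at or before entry")
    t_cal = entry + np.arange(n)
    idx = np.searchsorted(months, t_cal, side="right") - 1
    current = values[idx]
    lag = np.empty(n)
    lag[:LAG_MONTHS] = current[0]  # entry value before t=6
    if n > LAG_MONTHS:
        lag[LAG_MONTHS:] = current[: n - LAG_MONTHS]
    return current, lag


def expand_person_months(record: PatientRecord, outcome: str) -> list[PersonMonthRow]:
    """Expand one record into discrete-time rows, t = 0 .. exit.

    The final row carries the event flag if the event occurred, otherwise a
    censoring flag (``censor_ltf`` marks LTF censoring in the rebound
    analysis).
    """
    cols = _expand_arrays(record, outcome)
    female = record.gender == "female"
    who34 = record.who_stage == "III/IV"
    return [
        PersonMonthRow(
            patient_id=record.patient_id,
            t=int(cols["t"][i]),
            in_club=bool(cols["in_club"][i]),
            cd4_current=float(cols["cd4_current"][i]),
            cd4_lag6=float(cols["cd4_lag6"][i]),
            vl_suppressed=bool(cols["vl_suppressed"][i]),
            y=bool(cols["y"][i]),
            censored=bool(cols["censored"][i]),
            censor_ltf=bool(cols["censor_ltf"][i]),
            age_entry=record.age_entry,
            female=female,
            cd4_art_start=record.cd4_art_start,
            cd4_entry=record.cd4_entry,
            vl_suppressed_entry=record.vl_suppressed_entry,
            art_duration_entry=record.art_duration_entry,
            who_stage34=who34,
        )
        for i in range(len(cols["t"]))
    ]


def apply_itt_carry_forward(
    rows: list[PersonMonthRow], club_entry_month: int | None, entry_month: int = 0
) -> list[PersonMonthRow]:
    """Set ``in_club`` false strictly before club entry and true from the
    club-entry month onward; absent club entry -> all false.  Rows must be
    sorted by t."""
    t = np.array([r.t for r in rows])
    flags = _itt_indicator(t, club_entry_month, entry_month)
    for r, f in zip(rows, flags):
        r.in_club = bool(f)
    return rows


def locf_and_lag_covariates(
    rows: list[PersonMonthRow],
    cd4_series: Sequence[tuple[int, float]],
    vl_series: Sequence[tuple[int, bool]],
    entry_month: int = 0,
) -> list[PersonMonthRow]:
    """Fill cd4_current / cd4_lag6 / vl_suppressed on rows by LOCF + lag."""
    n = len(rows)
    pid = rows[0].patient_id if rows else "?"
    cd4, cd4lag = _locf_lag(cd4_series, entry_month, n, pid, "CD4")
    vl, _ = _locf_lag([(m, float(v)) for m, v in vl_series], entry_month, n, pid, "viral load")
    for i, r in enumerate(rows):
        r.cd4_current = float(cd4[i])
        r.cd4_lag6 = float(cd4lag[i])
        r.vl_suppressed = bool(vl[i])
    return rows


def person_month_table(cohort: Iterable[PatientRecord], outcome: str) -> pd.DataFrame:
    """Expand a whole cohort into one DataFrame (PERSON_MONTH_COLUMNS order).

    For ``outcome="rebound"`` patients not suppressed at entry are excluded
    (the analysis restriction), and an error is raised if none qualify.
    """
    records = list(cohort)
    if outcome == "rebound":
        records = [r for r in records if r.vl_suppressed_entry]
        if not records:
            raise ValueError(
                "rebound analysis requires patients virologically suppressed at study entry; "
                "none found"
            )
    parts: dict[str, list[np.ndarray]] = {c: [] for c in PERSON_MONTH_COLUMNS}
    for rec in records:
        cols = _expand_arrays(rec, outcome)
        n = len(cols["t"])
        parts["patient_id"].append(np.repeat(rec.patient_id, n))
        for c in ("t", "in_club", "cd4_current", "cd4_lag6", "vl_suppressed", "y",
                  "censored", "censor_ltf"):
            parts[c].append(cols[c])
        parts["age_entry"].append(np.repeat(rec.age_entry, n))
        parts["female"].append(np.repeat(rec.gender == "female", n))
        parts["cd4_art_start"].append(np.repeat(rec.cd4_art_start, n))
        parts["cd4_entry"].append(np.repeat(rec.cd4_entry, n))
        parts["vl_suppressed_entry"].append(np.repeat(rec.vl_suppressed_entry, n))
        parts["art_duration_entry"].append(np.repeat(rec.art_duration_entry, n))
        parts["who_stage34"].append(np.repeat(rec.who_stage == "III/IV", n))
    data = {c: np.concatenate(v) for c, v in parts.items()}
    return pd.DataFrame(data, columns=PERSON_MONTH_COLUMNS)


# ---------------------------------------------------------------------------
# CSV I/O

_BASELINE_COLUMNS = [
    "patient_id", "age_entry", "gender", "cd4_art_start", "cd4_entry",
    "vl_suppressed_entry", "art_duration_entry", "who_stage", "entry_month",
    "club_entry_month", "death_ltf_month", "rebound_month", "admin_censor_month",
]


def write_cohort_csv(cohort: Iterable[PatientRecord], baseline_path, measurements_path) -> None:
    base_rows = []
    meas_rows = []
    for r in cohort:
        base_rows.append({
            "patient_id": r.patient_id,
            "age_entry": r.age_entry,
            "gender": r.gender,
            "cd4_art_start": r.cd4_art_start,
            "cd4_entry": r.cd4_entry,
            "vl_suppressed_entry": int(r.vl_suppressed_entry),
            "art_duration_entry": r.art_duration_entry,
            "who_stage": r.who_stage,
            "entry_month": r.entry_month,
            "club_entry_month": "" if r.club_entry_month is None else r.club_entry_month,
            "death_ltf_month": "" if r.event_month_death_ltf is None else r.event_month_death_ltf,
            "rebound_month": "" if r.event_month_rebound is None else r.event_month_rebound,
            "admin_censor_month": r.admin_censor_month,
        })
        for m, v in r.cd4_series:
            meas_rows.append({"patient_id": r.patient_id, "month": m,
                              "variable": "cd4", "value": v})
        for m, v in r.vl_series:
            meas_rows.append({"patient_id": r.patient_id, "month": m,
                              "variable": "vl_suppressed", "value": int(v)})
    pd.DataFrame(base_rows, columns=_BASELINE_COLUMNS).to_csv(baseline_path, index=False)
    pd.DataFrame(meas_rows, columns=["patient_id", "month", "variable", "value"]).to_csv(
        measurements_path, index=False
    )


def read_cohort_csv(baseline_path, measurements_path) -> list[PatientRecord]:
    base = pd.read_csv(baseline_path, dtype={"patient_id": str})
    missing = set(_BASELINE_COLUMNS) - set(base.columns)
    if missing:
        raise ValueError(f"baseline file missing columns: {sorted(missing)}")
    meas = pd.read_csv(measurements_path, dtype={"patient_id": str})
    missing = {"patient_id", "month", "variable", "value"} - set(meas.columns)
    if missing:
        raise ValueError(f"measurements file missing columns: {sorted(missing)}")

    cd4_by_pid: dict[str, list] = {}
    vl_by_pid: dict[str, list] = {}
    for pid, month, var, val in meas[["patient_id", "month", "variable", "value"]].itertuples(
        index=False
    ):
        if var == "cd4":
            cd4_by_pid.setdefault(pid, []).append((int(month), float(val)))
        elif var == "vl_suppressed":
            vl_by_pid.setdefault(pid, []).append((int(month), bool(int(val))))
        else:
            raise ValueError(f"unknown measurement variable {var!r}")

    def _opt(v):
        return None if pd.isna(v) else int(v)

    records = []
    for row in base.itertuples(index=False):
        entry = int(row.entry_month)
        rec = PatientRecord(
            patient_id=row.patient_id,
            age_entry=float(row.age_entry),
            gender=str(row.gender),
            cd4_art_start=float(row.cd4_art_start),
            cd4_entry=float(row.cd4_entry),
            vl_suppressed_entry=bool(int(row.vl_suppressed_entry)),
            art_duration_entry=float(row.art_duration_entry),
            who_stage=str(row.who_stage),
            entry_month=entry,
            admin_censor_month=int(row.admin_censor_month),
            cd4_series=sorted(cd4_by_pid.get(row.patient_id, [])),
            vl_series=sorted(vl_by_pid.get(row.patient_id, [])),
            club_entry_month=_opt(row.club_entry_month),
            event_month_death_ltf=_opt(row.death_ltf_month),
            event_month_rebound=_opt(row.rebound_month),
            art_start_month=entry - int(round(float(row.art_duration_entry))),
        )
        records.append(rec)
    return records
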
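"""Crude event rates, exact Poisson intervals, rate ratios, and stratified
baseline summary tables.

Rates are events per 1000 person-years with exact (Garwood) chi-square
confidence limits; rate-ratio intervals use the log-scale 1/k_a + 1/k_b
variance.  Person-time is computed from the person-month table (rows/12)
and, in stratified summaries, split between in-club and not-in-club at the
month of club entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

__all__ = [
    "RateEstimate",
    "RateRatio",
    "crude_rate",
    "rate_ratio",
    "outcome_proportion",
    "table_one",
    "render_table_one",
]


@dataclass(frozen=True)
class RateEstimate:
    events: int | None
    person_years: float | None
    rate: float  # per 1000 person-years
    ci_low: float | None = None
    ci_high: float | None = None

    def rounded(self, ndigits: int = 1) -> tuple:
        return (
            round(self.rate, ndigits),
            None if self.ci_low is None else round(self.ci_low, ndigits),
            None if self.ci_high is None else round(self.ci_high, ndigits),
        )


@dataclass(frozen=True)
class RateRatio:
    numerator: RateEstimate
    denominator: RateEstimate
    ratio: float
    ci_low: float | None = None
    ci_high: float | None = None


def crude_rate(events: int, person_years: float, alpha: float = 0.05) -> RateEstimate:
    """Rate per 1000 person-years with the exact (Garwood) Poisson CI:
    lower = chi2(alpha/2, 2k)/2 / T, upper = chi2(1-alpha/2, 2k+2)/2 / T;
    zero events give a lower bound of 0."""
    if person_years <= 0:
        raise ValueError(f"person_years must be positive, got {person_years}")
    if events < 0:
        raise ValueError("events must be non-negative")
    k = int(events)
    lower = 0.0 if k == 0 else chi2.ppf(alpha / 2, 2 * k) / 2 / person_years
    upper = chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2 / person_years
    return RateEstimate(
        events=k,
        person_years=float(person_years),
        rate=1000.0 * k / person_years,
        ci_low=1000.0 * lower,
        ci_high=1000.0 * upper,
    )


def _as_rate(x) -> RateEstimate:
    if isinstance(x, RateEstimate):
        return x
    return RateEstimate(events=None, person_years=None, rate=float(x))


def rate_ratio(rate_a, rate_b, alpha: float = 0.05) -> RateRatio:
    """Ratio of two rates (per 1000 py); accepts RateEstimate objects or
    bare rates.  The CI (log scale, variance 1/k_a + 1/k_b) requires event
    counts on both sides and both counts positive."""
    a, b = _as_rate(rate_a), _as_rate(rate_b)
    if b.rate == 0:
        raise ZeroDivisionError("denominator rate is zero")
    ratio = a.rate / b.rate
    lo = hi = None
    if a.events and b.events:
        se = np.sqrt(1.0 / a.events + 1.0 / b.events)
        z = norm.ppf(1 - alpha / 2)
        lo = ratio * np.exp(-z * se)
        hi = ratio * np.exp(z * se)
    return RateRatio(a, b, ratio, lo, hi)


def outcome_proportion(event_counts, denominator: int, ndigits: int = 1) -> float:
    """Percentage of the denominator experiencing any of the counted events,
    rounded to ``ndigits`` decimal places."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    counts = np.atleast_1d(np.asarray(event_counts, dtype=float))
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total > denominator:
        raise ValueError(f"counts sum {total} exceeds denominator {denominator}")
    return round(100.0 * total / denominator, ndigits)


# ---------------------------------------------------------------------------
# stratified baseline summary

_STRATA = {
    "age": ("age_entry", [(-np.inf, 25, "<25"), (25, 35, "25-34"),
                          (35, 45, "35-44"), (45, np.inf, ">=45")]),
    "gender": ("female", [(0.5, 1.5, "female"), (-0.5, 0.5, "male")]),
    "cd4_art_start": ("cd4_art_start", [(-np.inf, 50, "<50"), (50, 100, "50-99"),
                                        (100, 200, "100-199"), (200, np.inf, ">=200")]),
    "cd4_entry": ("cd4_entry", [(-np.inf, 50, "<50"), (50, 100, "50-99"),
                                (100, 200, "100-199"), (200, np.inf, ">=200")]),
    "art_duration": ("art_duration_entry", [(-np.inf, 24, "<24"), (24, 48, "25-48"),
                                            (48, np.inf, ">48")]),
    "vl_suppressed_entry": ("vl_suppressed_entry", [(0.5, 1.5, "yes"), (-0.5, 0.5, "no")]),
    "who_stage": ("who_stage34", [(-0.5, 0.5, "I/II"), (0.5, 1.5, "III/IV")]),
}


def _split_rates(sub: pd.DataFrame) -> dict:
    """Crude in-club / not-in-club rates with person-time split at club entry."""
    out = {}
    for label, mask in (("in_club", sub["in_club"].astype(bool)),
                        ("not_in_club", ~sub["in_club"].astype(bool))):
        rows = sub.loc[mask]
        py = len(rows) / 12.0
        events = int(rows["y"].sum())
        if py > 0:
            r = crude_rate(events, py)
            out[f"{label}_events"] = events
            out[f"{label}_py"] = py
            out[f"{label}_rate"] = r.rate
            out[f"{label}_ci_low"] = r.ci_low
            out[f"{label}_ci_high"] = r.ci_high
        else:
            out[f"{label}_events"] = 0
            out[f"{label}_py"] = 0.0
            out[f"{label}_rate"] = np.nan
            out[f"{label}_ci_low"] = np.nan
            out[f"{label}_ci_high"] = np.nan
    return out


def table_one(person_months: pd.DataFrame, strata=None) -> pd.DataFrame:
    """Stratified baseline summary with crude event rates by club status.

    One row per stratum level: N (patients), %, events and person-years in
    and out of club (a joiner's person-time before club entry counts as
    not-in-club).  ``strata`` defaults to all known stratification
    variables; unknown names raise."""
    strata = list(_STRATA) if strata is None else list(strata)
    unknown = [s for s in strata if s not in _STRATA]
    if unknown:
        raise KeyError(f"unknown stratum variable(s): {unknown}")

    baseline = person_months.drop_duplicates("patient_id")
    n_total = len(baseline)
    rows = []
    overall = {"stratum": "all", "level": "all", "n": n_total, "pct": 100.0}
    overall.update(_split_rates(person_months))
    rows.append(overall)
    for name in strata:
        col, bands = _STRATA[name]
        values = baseline.set_index("patient_id")[col].astype(float)
        for lo, hi, label in bands:
            pids = values.index[(values >= lo) & (values < hi)]
            sub = person_months[person_months["patient_id"].isin(set(pids))]
            rec = {
                "stratum": name,
                "level": label,
                "n": len(pids),
                "pct": round(100.0 * len(pids) / n_total, 1) if n_total else np.nan,
            }
            if len(pids):
                rec.update(_split_rates(sub))
            else:
                rec.update({k: (0 if k.endswith("events") else np.nan)
                            for k in _split_rates(person_months)})
            rows.append(rec)
    return pd.DataFrame(rows)


def render_table_one(table: pd.DataFrame) -> str:
    """Monospaced text rendering of a table_one frame."""
    lines = [f"{'stratum':<20}{'level':<10}{'N':>6}{'%':>7}"
             f"{'in-club rate':>22}{'not-in-club rate':>22}"]
    for _, r in table.iterrows():
        def fmt(prefix):
            if pd.isna(r[f"{prefix}_rate"]):
                return "-"
            return (f"{r[f'{prefix}_rate']:.1f} "
                    f"({r[f'{prefix}_ci_low']:.1f}-{r[f'{prefix}_ci_high']:.1f})")
        lines.append(
            f"{r['stratum']:<20}{r['level']:<10}{r['n']:>6}{r['pct']:>7.1f}"
            f"{fmt('in_club'):>22}{fmt('not_in_club'):>22}"
        )
    return "\n".join(lines)
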
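"""End-to-end analysis orchestration: cohort -> person-months -> stabilized
weights -> weighted and unweighted hazard-ratio fits -> descriptives.

Used by the CLI and by the simulation-recovery tests; keeps the per-outcome
covariate conventions in one place (the rebound analysis is restricted to
patients suppressed at entry, so the entry-suppression and current-
suppression covariates are degenerate there and are dropped, and death/LTF
acts as censoring corrected by IPC weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PatientRecord, person_month_table
from .design import BASELINE_COVARIATES, TIME_VARYING_COVARIATES, SplineBasisSpec
from .msm import MSMFit, fit_unweighted_comparator, fit_weighted_pooled_logistic
from .rates import crude_rate, rate_ratio, table_one
from .weights import (
    EventModelFit,
    WeightSeries,
    compute_censoring_weights,
    compute_stabilized_iptw,
    fit_censoring_model,
    fit_treatment_model,
    weight_diagnostics,
)

__all__ = ["AnalysisResult", "analyze_cohort", "covariate_sets"]


def covariate_sets(outcome: str) -> tuple[list, list]:
    """(baseline, time-varying) covariate names for a given outcome."""
    baseline = list(BASELINE_COVARIATES)
    timevarying = list(TIME_VARYING_COVARIATES)
    if outcome == "rebound":
        baseline.remove("vl_suppressed_entry")
        timevarying.remove("vl_suppressed")
    return baseline, timevarying


@dataclass
class AnalysisResult:
    outcome: str
    person_months: pd.DataFrame
    weights: WeightSeries
    weighted_fit: MSMFit
    unweighted_fit: MSMFit
    crude_fit: MSMFit
    treatment_model: EventModelFit
    weight_summary: dict
    censoring_models: tuple | None = None
    table1: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    @property
    def combined_weights(self) -> np.ndarray:
        return self.weights.combined.to_numpy()


def analyze_cohort(
    cohort: list[PatientRecord],
    outcome: str = "death_ltf",
    post_join: str = "freeze",
    with_table1: bool = True,
) -> AnalysisResult:
    """Run the full estimation chain for one outcome.

    Fits the treatment (and, for rebound, censoring) weight models, builds
    stabilized weights, and returns the weighted MSM fit alongside the
    baseline-adjusted unweighted comparator and a crude (club + time only)
    fit.
    """
    pm = person_month_table(cohort, outcome)
    baseline, timevarying = covariate_sets(outcome)
    spline = SplineBasisSpec.from_months(pm["t"].to_numpy(dtype=float))

    den_model = fit_treatment_model(pm, baseline + timevarying, spline)
    num_model = fit_treatment_model(pm, baseline, spline)
    wt = compute_stabilized_iptw(pm, den_model, num_model, post_join=post_join)

    censoring_models = None
    if outcome == "rebound" and pm["censor_ltf"].any():
        cden = fit_censoring_model(pm, baseline + timevarying, spline, include_club=True)
        cnum = fit_censoring_model(pm, baseline, spline, include_club=True)
        wc = compute_censoring_weights(pm, cden, cnum)
        wt = wt.multiply(wc)
        censoring_models = (cden, cnum)

    w = wt.combined.to_numpy()
    weighted = fit_weighted_pooled_logistic(pm, w, baseline, spline)
    unweighted = fit_unweighted_comparator(pm, baseline, spline)
    crude = fit_unweighted_comparator(pm, [], spline)

    summary = weight_diagnostics(w, t=pm["t"].to_numpy())
    summary["iptw_only_mean"] = float(wt.sw.mean())
    summary["n_flagged_rows"] = int(len(wt.flagged_rows))

    return AnalysisResult(
        outcome=outcome,
        person_months=pm,
        weights=wt,
        weighted_fit=weighted,
        unweighted_fit=unweighted,
        crude_fit=crude,
        treatment_model=den_model,
        weight_summary=summary,
        censoring_models=censoring_models,
        table1=table_one(pm) if with_table1 else None,
    )


def crude_rate_ratio(person_months: pd.DataFrame):
    """Crude in-club vs not-in-club rate ratio from the person-month table."""
    in_club = person_months["in_club"].astype(bool)
    a = crude_rate(int(person_months.loc[in_club, "y"].sum()),
                   in_club.sum() / 12.0)
    b = crude_rate(int(person_months.loc[~in_club, "y"].sum()),
                   (~in_club).sum() / 12.0)
    return rate_ratio(a, b)
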
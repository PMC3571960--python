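"""Stabilized inverse-probability-of-treatment and censoring weights.

The treatment (club-entry) model is a pooled logistic regression for first
participation, fitted on the person-months at which no club participation
has yet occurred (each joiner's initiation month is the event row).  The
stabilized weight multiplies, over a patient's pre-initiation months, the
ratio of numerator to denominator probabilities of the observed treatment
state; from the initiation month onward the monthly factor is one and the
cumulative weight is frozen (``post_join="reset"`` instead resets it to
exactly one).  Censoring weights for the rebound analysis are the analogous
cumulative products for remaining uncensored by loss to follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._logistic import ConvergenceError, irls_logistic
from .design import (
    BASELINE_COVARIATES,
    TIME_VARYING_COVARIATES,
    SplineBasisSpec,
    design_matrix,
)

__all__ = [
    "WeightModelSpec",
    "WeightSeries",
    "EventModelFit",
    "fit_treatment_model",
    "fit_censoring_model",
    "compute_stabilized_iptw",
    "compute_censoring_weights",
    "truncate_weights",
    "weight_diagnostics",
    "at_risk_of_initiation",
]

PROBABILITY_FLOOR = 1e-6


@dataclass(frozen=True)
class WeightModelSpec:
    """Covariate sets for the denominator and numerator weight models."""

    denominator: tuple = tuple(BASELINE_COVARIATES + TIME_VARYING_COVARIATES)
    numerator: tuple = tuple(BASELINE_COVARIATES)
    time: str = "spline"  # "spline" | "linear"

    def __post_init__(self):
        extra = set(self.numerator) - set(self.denominator)
        if extra:
            raise ValueError(
                f"numerator covariates must be a subset of denominator covariates; "
                f"extra: {sorted(extra)}"
            )


@dataclass
class EventModelFit:
    """Pooled logistic model for a monthly event probability."""

    names: list[str]
    params: np.ndarray
    cov: np.ndarray
    covariates: tuple
    spline_spec: SplineBasisSpec | None
    include_club: bool = False
    n_rows: int = 0
    n_events: int = 0

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = design_matrix(df, self.covariates, self.spline_spec,
                             include_club=self.include_club)
        from scipy.special import expit

        return expit(X @ self.params)

    def odds_ratios(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        from scipy.stats import norm

        z = norm.ppf(0.975)
        return pd.DataFrame({
            "covariate": self.names,
            "or": np.exp(self.params),
            "ci_low": np.exp(self.params - z * se),
            "ci_high": np.exp(self.params + z * se),
            "p_value": 2 * norm.sf(np.abs(self.params / se)),
        })


def at_risk_of_initiation(person_months: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Boolean masks (at_risk, join) over the table.

    A row is at risk while no club participation occurred through the
    previous month; the initiation month itself is at risk with join=True.
    Assumes rows sorted by t within patient.
    """
    prev = person_months.groupby("patient_id", sort=False)["in_club"].shift(
        fill_value=False
    ).astype(bool)
    at_risk = ~prev
    join = person_months["in_club"].astype(bool) & at_risk
    return at_risk, join


def _fit_pooled_logistic(
    df: pd.DataFrame, event: np.ndarray, covariates, spline_spec, label: str,
    include_club: bool = False,
) -> EventModelFit:
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError(f"cannot fit {label} model: no events (zero initiations "
                         "or censorings) in the fitting sample")
    if isinstance(spline_spec, str) and spline_spec == "auto":
        spline_spec = SplineBasisSpec.from_months(df["t"].to_numpy(dtype=float))
    X, names = design_matrix(df, covariates, spline_spec, include_club=include_club)
    try:
        res = irls_logistic(X, event.astype(float))
    except ConvergenceError as exc:
        raise ValueError(
            f"{label} model did not converge ({exc}); "
            f"n_rows={len(df)}, n_events={n_events}"
        ) from exc
    return EventModelFit(
        names=names,
        params=res.params,
        cov=res.cov,
        covariates=tuple(covariates),
        spline_spec=spline_spec,
        include_club=include_club,
        n_rows=len(df),
        n_events=n_events,
    )


def fit_treatment_model(
    person_months: pd.DataFrame,
    covariates=tuple(BASELINE_COVARIATES + TIME_VARYING_COVARIATES),
    spline_spec: SplineBasisSpec | str | None = "auto",
) -> EventModelFit:
    """Pooled logistic model for first club participation, fitted on the
    pre-initiation person-months (initiation month included as event row).

    ``spline_spec="auto"`` derives percentile knots from the fitting rows;
    ``None`` omits follow-up-time terms entirely."""
    at_risk, join = at_risk_of_initiation(person_months)
    df = person_months.loc[at_risk]
    return _fit_pooled_logistic(
        df, join.loc[at_risk].to_numpy(), covariates, spline_spec, "treatment"
    )


def fit_censoring_model(
    person_months: pd.DataFrame,
    covariates,
    spline_spec: SplineBasisSpec | str | None = "auto",
    include_club: bool = True,
) -> EventModelFit:
    """Pooled logistic model for being censored by LTF in a given month."""
    event = person_months["censor_ltf"].to_numpy(dtype=bool)
    return _fit_pooled_logistic(
        person_months, event, covariates, spline_spec, "censoring",
        include_club=include_club,
    )


@dataclass
class WeightSeries:
    """Per person-month stabilized weights keyed by (patient_id, t).

    ``sw`` is the cumulative stabilized treatment weight, ``swc`` the
    cumulative censoring weight (1 where not applicable), ``combined`` their
    product.  ``flagged_rows`` lists rows whose denominator probability of
    the observed state fell below the floor (clipped, not dropped).
    """

    table: pd.DataFrame
    flagged_rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def sw(self) -> pd.Series:
        return self.table["sw"]

    @property
    def swc(self) -> pd.Series:
        return self.table["swc"]

    @property
    def combined(self) -> pd.Series:
        return self.table["combined"]

    def multiply(self, other: "WeightSeries") -> "WeightSeries":
        """Combine treatment and censoring weights row-wise."""
        t = self.table.copy()
        t["swc"] = self.table["swc"].to_numpy() * other.table["combined"].to_numpy()
        t["combined"] = t["sw"].to_numpy() * t["swc"].to_numpy()
        return WeightSeries(t, pd.concat([self.flagged_rows, other.flagged_rows]))


def _cumulative(person_months: pd.DataFrame, factor: np.ndarray) -> np.ndarray:
    return (
        pd.Series(factor, index=person_months.index)
        .groupby(person_months["patient_id"], sort=False)
        .cumprod()
        .to_numpy()
    )


def compute_stabilized_iptw(
    person_months: pd.DataFrame,
    denominator_model: EventModelFit,
    numerator_model: EventModelFit,
    post_join: str = "freeze",
    floor: float = PROBABILITY_FLOOR,
) -> WeightSeries:
    """Stabilized IPT weights: cumulative products of numerator/denominator
    probabilities of the observed club-entry state over pre-initiation
    months; monthly factor 1 afterwards.

    ``post_join="freeze"`` (default) keeps the cumulative weight at its
    initiation-month value; ``"reset"`` sets it to exactly 1 after joining.
    """
    if post_join not in ("freeze", "reset"):
        raise ValueError("post_join must be 'freeze' or 'reset'")
    at_risk, join = at_risk_of_initiation(person_months)
    ar = at_risk.to_numpy()
    jn = join.to_numpy()

    p_den = np.ones(len(person_months))
    p_num = np.ones(len(person_months))
    sub = person_months.loc[at_risk]
    p_den[ar] = denominator_model.predict(sub)
    p_num[ar] = numerator_model.predict(sub)

    obs_den = np.where(jn, p_den, 1.0 - p_den)
    obs_num = np.where(jn, p_num, 1.0 - p_num)
    low = ar & (obs_den < floor)
    flagged = person_months.loc[low, ["patient_id", "t"]].copy()
    if low.any():
        flagged["denominator_probability"] = obs_den[low]
    factor = np.ones(len(person_months))
    factor[ar] = obs_num[ar] / np.maximum(obs_den[ar], floor)

    sw = _cumulative(person_months, factor)
    if post_join == "reset":
        sw = np.where(ar, sw, 1.0)

    table = person_months[["patient_id", "t"]].copy()
    table["factor"] = factor
    table["sw"] = sw
    table["swc"] = 1.0
    table["combined"] = sw
    return WeightSeries(table, flagged)


def compute_censoring_weights(
    person_months: pd.DataFrame,
    censor_denominator_model: EventModelFit,
    censor_numerator_model: EventModelFit,
    floor: float = PROBABILITY_FLOOR,
) -> WeightSeries:
    """Stabilized inverse-probability-of-censoring weights: cumulative
    products of P(uncensored | baseline) / P(uncensored | history) over the
    months a patient remains uncensored by LTF (unit factor on the censored
    row itself)."""
    p_den = censor_denominator_model.predict(person_months)
    p_num = censor_numerator_model.predict(person_months)
    uncensored = ~person_months["censor_ltf"].to_numpy(dtype=bool)

    den = 1.0 - p_den
    low = uncensored & (den < floor)
    flagged = person_months.loc[low, ["patient_id", "t"]].copy()
    if low.any():
        flagged["denominator_probability"] = den[low]
    factor = np.ones(len(person_months))
    factor[uncensored] = (1.0 - p_num[uncensored]) / np.maximum(den[uncensored], floor)

    swc = _cumulative(person_months, factor)
    table = person_months[["patient_id", "t"]].copy()
    table["factor"] = factor
    table["sw"] = 1.0
    table["swc"] = swc
    table["combined"] = swc
    return WeightSeries(table, flagged)


def truncate_weights(weights, percentile_pair: tuple[float, float]):
    """Clip weights at the given percentiles of their own distribution.

    Returns (clipped array, report dict with counts and the new mean).
    """
    lo, hi = percentile_pair
    if not (0 <= lo < hi <= 100):
        raise ValueError(f"invalid percentile pair {percentile_pair}")
    w = np.asarray(weights, dtype=float)
    lo_v, hi_v = np.percentile(w, [lo, hi])
    clipped = np.clip(w, lo_v, hi_v)
    report = {
        "lower_percentile": lo,
        "upper_percentile": hi,
        "lower_value": float(lo_v),
        "upper_value": float(hi_v),
        "n_clipped_low": int((w < lo_v).sum()),
        "n_clipped_high": int((w > hi_v).sum()),
        "mean_before": float(w.mean()),
        "mean_after": float(clipped.mean()),
    }
    return clipped, report


def weight_diagnostics(weights, t=None, mean_tolerance: float = 0.1) -> dict:
    """Descriptive summary of a weight vector (mean, sd, percentiles,
    extremes, optional mean trajectory over follow-up time); flags a mean
    deviating from 1 by more than ``mean_tolerance``."""
    w = np.asarray(weights, dtype=float)
    if len(w) == 0:
        raise ValueError("empty weight vector")
    qs = [1, 5, 25, 50, 75, 95, 99]
    out = {
        "n": int(len(w)),
        "mean": float(w.mean()),
        "sd": float(w.std(ddof=1)) if len(w) > 1 else 0.0,
        "min": float(w.min()),
        "max": float(w.max()),
        "percentiles": {str(q): float(v) for q, v in zip(qs, np.percentile(w, qs))},
        "mean_deviates": bool(abs(w.mean() - 1.0) > mean_tolerance),
        "n_extreme": int(((w > 10) | (w < 0.1)).sum()),
    }
    if t is not None:
        traj = pd.Series(w).groupby(np.asarray(t)).mean()
        out["mean_by_month"] = {str(int(k)): float(v) for k, v in traj.items()}
    return out
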
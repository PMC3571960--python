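"""Design-matrix construction shared by the weight and outcome models.

Covariates are referred to by name; names ending in ``_per100`` / ``_per12``
rescale the underlying column, ``*_cat`` names expand to dummy bands, and
2-tuples denote pairwise interactions.  Follow-up time enters through a
restricted (natural) cubic spline with knots at percentiles of the observed
person-month times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SplineBasisSpec",
    "spline_basis",
    "design_matrix",
    "BASELINE_COVARIATES",
    "TIME_VARYING_COVARIATES",
]

#: Baseline covariate set of the outcome and numerator models.
BASELINE_COVARIATES = [
    "age_entry",
    "female",
    "cd4_art_start_per100",
    "cd4_entry_per100",
    "vl_suppressed_entry",
    "art_duration_per12",
    "who_stage34",
]

#: Additional time-varying covariates of the denominator (treatment) model.
TIME_VARYING_COVARIATES = [
    "cd4_current_per100",
    "cd4_lag6_per100",
    "vl_suppressed",
]

DEFAULT_KNOT_PERCENTILES = (5.0, 25.0, 50.0, 75.0, 95.0)


@dataclass(frozen=True)
class SplineBasisSpec:
    """Restricted cubic spline specification: fixed, strictly increasing knots."""

    knots: tuple[float, ...]

    def __post_init__(self):
        if len(self.knots) < 3:
            raise ValueError("restricted cubic spline needs at least 3 knots")
        if any(b <= a for a, b in zip(self.knots, self.knots[1:])):
            raise ValueError(
                f"knots must be strictly increasing, got {self.knots}; "
                "too few distinct time values — consider linear time"
            )

    @classmethod
    def from_months(cls, months, percentiles=DEFAULT_KNOT_PERCENTILES) -> "SplineBasisSpec":
        """Knots at percentiles of the person-month time distribution."""
        months = np.asarray(months, dtype=float)
        if len(np.unique(months)) < len(percentiles):
            raise ValueError(
                "fewer distinct month values than knots — consider linear time"
            )
        knots = np.percentile(months, percentiles)
        return cls(tuple(float(k) for k in knots))

    @property
    def n_columns(self) -> int:
        return len(self.knots) - 1


def spline_basis(x, spec: SplineBasisSpec) -> np.ndarray:
    """Restricted cubic basis: K knots -> K-1 columns (x plus K-2 nonlinear
    truncated-power terms), linear beyond the boundary knots.

    Nonlinear terms are scaled by (k_K - k_1)^2 for numerical balance; they
    all vanish at and below the first knot.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(spec.knots)
    K = len(k)
    cols = [x]
    denom = k[-1] - k[-2]
    scale = (k[-1] - k[0]) ** 2

    def cub(v):
        return np.clip(v, 0.0, None) ** 3

    for j in range(K - 2):
        term = (
            cub(x - k[j])
            - cub(x - k[-2]) * (k[-1] - k[j]) / denom
            + cub(x - k[-1]) * (k[-2] - k[j]) / denom
        )
        cols.append(term / scale)
    return np.column_stack(cols)


_CD4_BANDS = [(-np.inf, 50), (50, 100), (100, 200)]  # reference: >= 200
# entry CD4 is always > 200 under the eligibility rule, so its bands differ
_CD4_ENTRY_BANDS = [(-np.inf, 300), (300, 450)]  # reference: >= 450
_AGE_BANDS = [(-np.inf, 25), (25, 35), (35, 45)]  # reference: >= 45
_ART_BANDS = [(-np.inf, 24), (24, 48)]  # reference: > 48


def _banded(values: pd.Series, bands, label: str):
    names, cols = [], []
    v = values.to_numpy(dtype=float)
    for lo, hi in bands:
        names.append(f"{label}[{lo:g},{hi:g})")
        cols.append(((v >= lo) & (v < hi)).astype(float))
    return names, cols


def _column(df: pd.DataFrame, name: str):
    """Resolve one covariate name to (names, columns)."""
    if name.endswith("_per100"):
        base = name[: -len("_per100")]
        return [name], [df[base].to_numpy(dtype=float) / 100.0]
    if name.endswith("_per12"):
        base = name[: -len("_per12")]
        if base == "art_duration":
            base = "art_duration_entry"
        return [name], [df[base].to_numpy(dtype=float) / 12.0]
    if name == "cd4_entry_cat":
        return _banded(df["cd4_entry"], _CD4_ENTRY_BANDS, name)
    if name == "cd4_art_start_cat":
        return _banded(df["cd4_art_start"], _CD4_BANDS, name)
    if name == "cd4_current_cat":
        return _banded(df["cd4_current"], _CD4_BANDS, name)
    if name == "age_cat":
        return _banded(df["age_entry"], _AGE_BANDS, name)
    if name == "art_duration_cat":
        return _banded(df["art_duration_entry"], _ART_BANDS, name)
    return [name], [df[name].to_numpy(dtype=float)]


def design_matrix(
    df: pd.DataFrame,
    covariates,
    spline_spec: SplineBasisSpec | None = None,
    include_club: bool = False,
    time_col: str = "t",
) -> tuple[np.ndarray, list[str]]:
    """Assemble [intercept, (in_club), spline(t), covariates...].

    ``covariates`` entries are names or 2-tuples (interactions).  Returns
    the matrix and matching column names; the in-club indicator, when
    requested, is always column 1.
    """
    names = ["intercept"]
    cols = [np.ones(len(df))]
    if include_club:
        names.append("in_club")
        cols.append(df["in_club"].to_numpy(dtype=float))
    if spline_spec is not None:
        basis = spline_basis(df[time_col].to_numpy(dtype=float), spline_spec)
        for j in range(basis.shape[1]):
            names.append("time_spline_1" if j == 0 else f"time_spline_{j + 1}")
            cols.append(basis[:, j])
    for cov in covariates:
        if isinstance(cov, tuple):
            na, ca = _column(df, cov[0])
            nb, cb = _column(df, cov[1])
            for n1, c1 in zip(na, ca):
                for n2, c2 in zip(nb, cb):
                    names.append(f"{n1}:{n2}")
                    cols.append(c1 * c2)
        else:
            n_, c_ = _column(df, cov)
            names.extend(n_)
            cols.extend(c_)
    return np.column_stack(cols), names
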
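"""Synthetic longitudinal cohort generator with known causal ground truth.

The generator emulates the structure of an ART cohort in which clinically
stable patients are progressively offered group-based care ("clubs"):
healthier patients (higher CD4, virologically suppressed) preferentially
join, club membership carries forward (intention-to-treat), and the
death/loss-to-follow-up and virologic-rebound hazards depend on club status
and on the same time-varying covariates — the classic time-varying
confounding setup that inverse-probability weighting is designed to break.

All event processes are discrete-time Bernoulli hazards per month, exactly
matching the pooled-logistic analysis model, so parameter recovery is
well-posed.  :func:`oracle_marginal_hr` computes the true marginal hazard
ratio by counterfactual simulation (forced club entry at a randomized time
vs never) with common random numbers across arms.

Within-month ordering at month t: (1) CD4 random-walk update; (2)
suppression transition using club status at t-1 (a rebound event is the
first loss of suppression); (3) club-entry draw from CD4(t), suppression(t)
and baseline covariates; (4) death/LTF draw from club(t), CD4(t),
suppression(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np
from scipy.special import expit, logit

from .cohort import PatientRecord

__all__ = ["SimulationConfig", "preset", "simulate_cohort", "oracle_marginal_hr",
           "OracleResult", "PRESET_NAMES"]

PRESET_NAMES = ("null", "randomized", "confounded", "confounded_censoring")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters; log-odds scale for all hazard models."""

    n_patients: int = 2000
    max_follow_up: int = 40          # calendar closure month (entry at month 0 -> 41 rows)
    entry_stagger_max: int = 12      # entry month ~ Uniform{0..entry_stagger_max}

    # baseline covariate distributions
    p_female: float = 0.7
    p_who_stage34: float = 0.72
    p_suppressed_entry: float = 0.78
    age_mean: float = 35.0
    age_sd: float = 8.0
    cd4_art_start_shape: float = 2.0
    cd4_art_start_scale: float = 70.0
    cd4_entry_offset: float = 205.0   # entry CD4 = offset + Gamma(shape, scale), keeps >200
    cd4_entry_shape: float = 2.0
    cd4_entry_scale: float = 80.0
    art_duration_shape: float = 1.5   # entry ART months = 18 + Gamma(shape, scale)
    art_duration_scale: float = 18.0

    # CD4 dynamics (bounded random walk, floor 0)
    cd4_drift: float = 2.0
    cd4_sd: float = 25.0
    cd4_club_drift: float = 0.0       # treatment-affects-confounder stress knob; 0 by default

    # viral suppression dynamics (two-state Markov chain; a suppressed->unsuppressed
    # transition is the rebound event)
    rebound_base_prob: float = 0.006
    rebound_club_log_or: float = 0.0
    rebound_cd4_per100: float = -0.10  # centered at cd4/100 = 3
    supp_regain_prob: float = 0.15

    # monthly club-entry hazard (first participation)
    club_intercept: float = -9.8
    club_cd4_per100: float = 0.5
    club_supp: float = 1.6
    club_female: float = 0.3
    club_art_per12: float = 0.6
    club_time_per_month: float = -0.12  # rollout wave: entry hazard decays over follow-up

    # monthly death/LTF hazard; in the rebound analysis this process is the
    # (potentially informative) LTF censoring mechanism
    outcome_intercept: float = -1.2
    outcome_club_log_hr: float = math.log(0.45)
    outcome_cd4_per100: float = -0.4
    outcome_supp: float = -2.0
    outcome_art_per12: float = -0.35  # baseline-confounding channel

    oracle_entry_max_month: int = 14  # randomized entry-time distribution for the oracle
    rng_seed: int = 0

    def validate(self) -> None:
        bad = []
        for name in ("p_female", "p_who_stage34", "p_suppressed_entry",
                     "rebound_base_prob", "supp_regain_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(f"{name}={v} outside [0, 1]")
        if self.n_patients < 1:
            bad.append(f"n_patients={self.n_patients} < 1")
        if self.max_follow_up < 1:
            bad.append(f"max_follow_up={self.max_follow_up} < 1")
        if not (0 <= self.entry_stagger_max < self.max_follow_up):
            bad.append("entry_stagger_max must lie in [0, max_follow_up)")
        if expit(self.outcome_intercept) >= 0.5:
            bad.append("outcome_intercept implies monthly hazard >= 0.5")
        if self.rebound_base_prob >= 0.5:
            bad.append("rebound_base_prob >= 0.5")
        for name in ("age_sd", "cd4_sd", "cd4_art_start_shape", "cd4_art_start_scale",
                     "cd4_entry_shape", "cd4_entry_scale", "art_duration_shape",
                     "art_duration_scale"):
            if getattr(self, name) <= 0:
                bad.append(f"{name} must be positive")
        if bad:
            raise ValueError("invalid SimulationConfig: " + "; ".join(bad))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def preset(name: str, **overrides) -> SimulationConfig:
    """Documented parameter bundles.

    - ``null``: confounded club entry, but a truly null club effect on both
      outcomes.
    - ``randomized``: club entry independent of all covariates; protective
      club effect (log 0.5).
    - ``confounded``: healthier patients (higher CD4, suppressed women longer
      on ART) preferentially join; true conditional club effect log 0.45 on
      death/LTF, so the crude rate ratio exaggerates the protection.
    - ``confounded_censoring``: as ``confounded`` plus a protective club
      effect on virologic rebound and a steeper CD4/suppression gradient in
      the LTF hazard (informative censoring for the rebound analysis).
    """
    if name == "null":
        cfg = SimulationConfig(outcome_club_log_hr=0.0, rebound_club_log_or=0.0)
    elif name == "randomized":
        cfg = SimulationConfig(
            club_intercept=-3.8,
            club_cd4_per100=0.0, club_supp=0.0, club_female=0.0, club_art_per12=0.0,
            outcome_club_log_hr=math.log(0.5),
        )
    elif name == "confounded":
        cfg = SimulationConfig()
    elif name == "confounded_censoring":
        cfg = SimulationConfig(
            rebound_base_prob=0.012,
            rebound_club_log_or=math.log(0.4),
            rebound_cd4_per100=-0.5,
            outcome_cd4_per100=-0.6,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# core engine


@dataclass
class _SimArrays:
    """Raw simulation output; month index is follow-up time t (relative)."""

    entry: np.ndarray          # (n,) calendar entry month
    cap: np.ndarray            # (n,) last observable t (administrative closure)
    age: np.ndarray
    female: np.ndarray
    who34: np.ndarray
    cd4_art_start: np.ndarray
    art_duration: np.ndarray
    supp_entry: np.ndarray
    cd4: np.ndarray            # (n, T+1)
    supp: np.ndarray           # (n, T+1) bool
    club: np.ndarray           # (n, T+1) bool, monotone
    death_t: np.ndarray        # (n,) int, -1 if none (within death-truncated follow-up)
    rebound_t: np.ndarray      # (n,) int, -1 if none
    club_t: np.ndarray         # (n,) int, -1 if never


def _simulate(
    config: SimulationConfig,
    n: int,
    seed: int,
    policy: Literal["observational", "forced", "never"] = "observational",
    forced_entry: np.ndarray | None = None,
    apply_death: bool = True,
) -> _SimArrays:
    """Run the month loop.

    The random stream is consumed in an identical order for every policy and
    for ``apply_death`` on/off, so counterfactual arms run with common random
    numbers (identical confounder streams) when given the same seed.
    """
    rng = np.random.default_rng(seed)
    T = config.max_follow_up

    entry = rng.integers(0, config.entry_stagger_max + 1, n)
    cap = T - entry  # rows exist for t = 0..cap
    age = np.maximum(18.0, rng.normal(config.age_mean, config.age_sd, n))
    female = rng.random(n) < config.p_female
    who34 = rng.random(n) < config.p_who_stage34
    cd4_art_start = rng.gamma(config.cd4_art_start_shape, config.cd4_art_start_scale, n)
    cd4_entry = config.cd4_entry_offset + rng.gamma(
        config.cd4_entry_shape, config.cd4_entry_scale, n
    )
    art_duration = 18.0 + rng.gamma(config.art_duration_shape, config.art_duration_scale, n)
    supp_entry = rng.random(n) < config.p_suppressed_entry

    cd4 = np.zeros((n, T + 1))
    supp = np.zeros((n, T + 1), dtype=bool)
    club = np.zeros((n, T + 1), dtype=bool)
    death_t = np.full(n, -1)
    rebound_t = np.full(n, -1)
    club_t = np.full(n, -1)

    cd4[:, 0] = cd4_entry
    supp[:, 0] = supp_entry

    base_club_lp = (
        config.club_intercept
        + config.club_female * female
        + config.club_art_per12 * art_duration / 12.0
    )
    alive = np.ones(n, dtype=bool)

    for t in range(T + 1):
        # fixed draw order per month regardless of policy / survival status
        noise = rng.normal(0.0, config.cd4_sd, n)
        u_reb = rng.random(n)
        u_regain = rng.random(n)
        u_club = rng.random(n)
        u_out = rng.random(n)

        active = alive & (t <= cap)

        if t > 0:
            drift = config.cd4_drift + config.cd4_club_drift * club[:, t - 1]
            cd4[:, t] = np.maximum(0.0, cd4[:, t - 1] + drift + noise)
            p_down = expit(
                logit(config.rebound_base_prob)
                + config.rebound_club_log_or * club[:, t - 1]
                + config.rebound_cd4_per100 * (cd4[:, t] / 100.0 - 3.0)
            )
            was_supp = supp[:, t - 1]
            supp[:, t] = np.where(was_supp, u_reb >= p_down, u_regain < config.supp_regain_prob)
            newly_rebounded = active & was_supp & ~supp[:, t] & (rebound_t < 0)
            rebound_t[newly_rebounded] = t

        if policy == "observational":
            p_join = expit(
                base_club_lp
                + config.club_cd4_per100 * cd4[:, t] / 100.0
                + config.club_supp * supp[:, t]
                + config.club_time_per_month * t
            )
            prev = club[:, t - 1] if t > 0 else np.zeros(n, dtype=bool)
            joins = active & ~prev & (u_club < p_join)
            club[:, t] = prev | joins
            club_t[joins] = t
        elif policy == "forced":
            club[:, t] = t >= forced_entry
        else:  # never
            club[:, t] = False

        if apply_death:
            p_death = expit(
                config.outcome_intercept
                + config.outcome_club_log_hr * club[:, t]
                + config.outcome_cd4_per100 * cd4[:, t] / 100.0
                + config.outcome_supp * supp[:, t]
                + config.outcome_art_per12 * art_duration / 12.0
            )
            dies = active & (u_out < p_death)
            death_t[dies] = t
            alive &= ~dies

    if policy == "forced":
        club_t = np.where(forced_entry <= cap, forced_entry, -1)
    return _SimArrays(entry, cap, age, female, who34, cd4_art_start, art_duration,
                      supp_entry, cd4, supp, club, death_t, rebound_t, club_t)


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> list[PatientRecord]:
    """Generate a cohort of :class:`PatientRecord`; reproducible for a fixed
    config + seed (``seed=None`` uses ``config.rng_seed``)."""
    config.validate()
    if seed is None:
        seed = config.rng_seed
    n = config.n_patients
    s = _simulate(config, n, seed, "observational")

    records: list[PatientRecord] = []
    width = len(str(n - 1))
    for i in range(n):
        entry = int(s.entry[i])
        exit_t = int(s.death_t[i]) if s.death_t[i] >= 0 else int(s.cap[i])
        months = range(entry, entry + exit_t + 1)
        cd4_vals = s.cd4[i, : exit_t + 1]
        supp_vals = s.supp[i, : exit_t + 1]
        rebound_t = int(s.rebound_t[i])
        records.append(PatientRecord(
            patient_id=f"p{i:0{width}d}",
            age_entry=float(s.age[i]),
            gender="female" if s.female[i] else "male",
            cd4_art_start=float(s.cd4_art_start[i]),
            cd4_entry=float(s.cd4[i, 0]),
            vl_suppressed_entry=bool(s.supp_entry[i]),
            art_duration_entry=float(s.art_duration[i]),
            who_stage="III/IV" if s.who34[i] else "I/II",
            entry_month=entry,
            admin_censor_month=entry + int(s.cap[i]),
            cd4_series=[(m, round(float(v), 1)) for m, v in zip(months, cd4_vals)],
            vl_series=[(m, bool(v)) for m, v in zip(months, supp_vals)],
            club_entry_month=entry + int(s.club_t[i]) if s.club_t[i] >= 0 else None,
            event_month_death_ltf=entry + int(s.death_t[i]) if s.death_t[i] >= 0 else None,
            event_month_rebound=(
                entry + rebound_t
                if s.supp_entry[i] and rebound_t >= 0 and rebound_t <= exit_t
                else None
            ),
            art_start_month=entry - int(round(float(s.art_duration[i]))),
        ))
    return records


# ---------------------------------------------------------------------------
# counterfactual oracle


@dataclass
class OracleResult:
    hr: float
    log_hr: float
    se_log_hr: float

    def __float__(self) -> float:
        return self.hr


def oracle_marginal_hr(
    config: SimulationConfig,
    n_large: int = 100_000,
    seed: int = 0,
    outcome: str = "death_ltf",
    adjust_baseline: bool = True,
) -> OracleResult:
    """True marginal hazard ratio of club participation by counterfactual
    simulation.

    Two arms share identical confounder streams (common random numbers):
    one with club entry forced at a randomized month ~ Uniform{0..
    ``oracle_entry_max_month``}, one never joining.  The marginal HR is the
    club coefficient of an unconfounded pooled logistic fit (spline time)
    on the pooled counterfactual person-months.  With ``adjust_baseline``
    (default) the fit conditions on the same baseline covariates as the
    analysis model, so its estimand matches the weighted MSM's exactly
    (marginal over time-varying covariates, conditional on baseline); set
    it to False for the fully marginal contrast.  For ``outcome="rebound"``
    the arms are simulated without LTF censoring (the IPCW
    pseudo-population) and restricted to patients suppressed at entry.
    """
    from .msm import SplineBasisSpec, spline_basis  # local import to avoid cycle

    config.validate()
    entry_rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    forced = entry_rng.integers(0, config.oracle_entry_max_month + 1, n_large)

    apply_death = outcome == "death_ltf"
    arms = [
        _simulate(config, n_large, seed, "forced", forced_entry=forced,
                  apply_death=apply_death),
        _simulate(config, n_large, seed, "never", apply_death=apply_death),
    ]

    T = config.max_follow_up
    pid_parts, t_parts, a_parts, y_parts = [], [], [], []
    for s in arms:
        if outcome == "death_ltf":
            keep = np.ones(n_large, dtype=bool)
            exit_t = np.where(s.death_t >= 0, s.death_t, s.cap)
            event_t = s.death_t
        else:
            keep = s.supp_entry
            event_t = np.where(s.rebound_t >= 0, s.rebound_t, -1)
            exit_t = np.where(event_t >= 0, event_t, s.cap)
        for t in range(T + 1):
            active = np.nonzero(keep & (exit_t >= t))[0]
            if len(active) == 0:
                continue
            pid_parts.append(active)
            t_parts.append(np.full(len(active), t))
            a_parts.append(s.club[active, t].astype(float))
            y_parts.append((event_t[active] == t).astype(float))

    pid = np.concatenate(pid_parts)
    t_vals = np.concatenate(t_parts).astype(float)
    a_vals = np.concatenate(a_parts)
    y = np.concatenate(y_parts)

    basis = spline_basis(t_vals, SplineBasisSpec.from_months(t_vals))
    cols = [np.ones(len(y)), a_vals, basis]
    if adjust_baseline:
        s0 = arms[0]  # baseline draws identical across arms (common seed)
        baseline_cols = [
            s0.age[pid],
            s0.female[pid].astype(float),
            s0.cd4_art_start[pid] / 100.0,
            s0.cd4[pid, 0] / 100.0,
            s0.supp_entry[pid].astype(float),
            s0.art_duration[pid] / 12.0,
            s0.who34[pid].astype(float),
        ]
        if outcome == "rebound":
            del baseline_cols[4]  # entry suppression constant in restricted sample
        cols.extend(baseline_cols)
    X = np.column_stack(cols)

    from ._logistic import irls_logistic

    fit = irls_logistic(X, y)
    beta = float(fit.params[1])
    se = float(np.sqrt(fit.cov[1, 1]))
    return OracleResult(hr=math.exp(beta), log_hr=beta, se_log_hr=se)
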
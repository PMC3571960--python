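# cohortmsm

Marginal structural model (MSM) pipeline for discrete-time longitudinal
cohort data, built around the evaluation of a group-based care programme
("adherence clubs") for stable patients on long-term antiretroviral
therapy:

* **`cohortmsm.cohort`** — patient-level data model (baseline covariates,
  dated CD4/viral-load measurement series, club-entry / outcome / censoring
  months) and its expansion into a person-month table with
  intention-to-treat treatment carry-forward, last-observation-carried-
  forward covariates and a 6-month CD4 lag. Two outcomes: combined
  death/loss-to-follow-up, and virologic rebound (restricted to patients
  suppressed at entry, with LTF acting as censoring).
* **`cohortmsm.weights`** — pooled logistic treatment model for first club
  participation (fitted on pre-initiation person-months), stabilized
  inverse-probability-of-treatment weights (monthly factor 1 with the
  cumulative weight frozen after initiation), stabilized censoring (IPC)
  weights for the rebound analysis, percentile truncation and diagnostics.
* **`cohortmsm.msm`** — weighted pooled logistic hazard model with
  restricted cubic spline follow-up time (knots at the 5/25/50/75/95th
  percentiles), patient-clustered sandwich variance with a G/(G−1)
  correction, Wald CIs on the log-HR scale, an unweighted comparator and a
  sensitivity suite (weight truncation, categorized covariates,
  interactions).
* **`cohortmsm.rates`** — crude rates per 1000 person-years with exact
  (Garwood) Poisson confidence intervals, crude rate ratios, outcome
  proportions and a stratified baseline summary table with person-time
  split at club entry.
* **`cohortmsm.simulate`** — synthetic cohort generator with the study's
  confounding structure (healthier patients preferentially join clubs;
  outcomes depend on club status and the same covariates) and a
  counterfactual oracle for the true marginal hazard ratio, enabling
  full parameter-recovery testing without any external data.
* **`cohortmsm.pipeline` / `cohortmsm.cli`** — end-to-end orchestration.

## CLI

```bash
# generate a synthetic cohort (CSV schema + manifest)
cohortmsm simulate --preset confounded --n 2000 --seed 1 --out scratch/cohort

# run the full analysis for one outcome
cohortmsm analyze \
    --baseline scratch/cohort/baseline.csv \
    --measurements scratch/cohort/measurements.csv \
    --outcome death_ltf --truncate 1,99 --out scratch/report
```

`analyze` writes weights, weight diagnostics, weighted and unweighted MSM
fits, a weighted-vs-unweighted comparison, a stratified baseline summary, a
sensitivity table and a manifest. Exit codes: 0 success, 1 validation
error, 2 runtime error.

## Data formats

Cohorts are exchanged as two CSV files: a baseline table (one row per
patient: `patient_id, age_entry, gender, cd4_art_start, cd4_entry,
vl_suppressed_entry, art_duration_entry, who_stage, entry_month,
club_entry_month, death_ltf_month, rebound_month, admin_censor_month`)
and a long measurements table (`patient_id, month, variable, value` with
`variable` in `{cd4, vl_suppressed}`). All dates are integer calendar-month
indices. The person-month table column set is fixed and documented in
`cohortmsm.cohort.PERSON_MONTH_COLUMNS`.
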
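# ccwmi

Clone-censor-weight trial emulation with inverse-probability-of-censoring
weighted discrete-time hazard models and reference-based multiple
imputation (RBMI) for informative loss to follow-up.

The package emulates a two-arm target trial comparing prophylaxis-stopping
strategies from long-format longitudinal cohort data:

- **`ccwmi.synthetic_cohort`** — a configurable cohort simulator (monthly
  CD4 / HIV-RNA trajectories, prophylaxis behaviour, a composite
  event-or-death process, and loss to follow-up that can be made
  informative or non-informative) with a known ground-truth regime effect.
- **`ccwmi.trial_emulation`** — eligibility screening, time-0 definition,
  duplication of every eligible patient into both stopping regimes
  (regime 1: CD4 > 200 cells/µL for more than 3 months; regime 2: two
  consecutive HIV-RNA measurements < 400 copies/ml), and per-month
  compliance evaluation with censoring at first non-compliance.
- **`ccwmi.censoring_weights`** — per-arm stabilized IPC weights
  (cumulative numerator/denominator ratios, percentile truncation,
  positivity checks).
- **`ccwmi.discrete_time_outcome`** — weighted pooled logistic regression
  `logit h(t) = β₀ + β₁t + β₂t² + β₃t³ + θ·arm + γ·t·arm`, hazard-ratio
  summaries (main-effect or time-averaged), patient-level bootstrap CIs,
  and survival curves.
- **`ccwmi.reference_mi`** — multiple imputation of post-LTFU event
  histories under CAR (cross-check), "jump to off prophylaxis" on both
  arms, or on arm 2 only, pooled by Rubin's rules with Barnard–Rubin
  degrees of freedom.
- **`ccwmi.pipeline` / `ccwmi.cli`** — run orchestration, descriptive
  tables (counts, percentages, two-proportion chi-square p-values) and a
  `ccwmi` command-line interface.

## Command-line usage

```bash
# simulate a cohort from a YAML config
ccwmi simulate --config examples/config.yaml --out cohort.csv

# screen, clone and censor
ccwmi emulate --cohort cohort.csv --out clones.csv

# descriptive table
ccwmi report --clones clones.csv

# full pipeline: primary IPW analysis + MI scenarios
ccwmi analyze --config examples/config.yaml --scenario car --scenario j2op \
    --m 25 --out runs/demo
```

A config file looks like:

```yaml
cohort:
  n_patients: 2000
  seed: 1
  log_hazard_intercept: -5.0
  log_hr_off_prophylaxis: 0.5
  log_hr_regime: -0.25
  ltfu_monthly_probability: 0.01
grace: 1
weights:
  truncation_percentile: 99
outcome:
  hr_method: main-effect
  bootstrap_reps: 0
mi:
  scenarios: [car, j2op, j2op-arm2]
  m: 25
seed: 1
```

Use `cohort_path: my_cohort.csv` instead of the `cohort:` block to analyze
an existing file (comma-separated, header row, one patient-month per line
with columns `patient_id, month, cd4, rna, on_prophylaxis, on_cart,
event_pcp, event_death, ltfu_after`).

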
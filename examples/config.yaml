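# Example run configuration for `ccwmi simulate` / `ccwmi analyze`.
cohort:
  n_patients: 2000
  max_months: 60
  seed: 1
  log_hazard_intercept: -5.0
  log_hr_off_prophylaxis: 0.5
  log_hr_regime: -0.25
  ltfu_monthly_probability: 0.01
  ltfu_informative_log_or: 0.0
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
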
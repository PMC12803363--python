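# trajimpute

Local windowed multiple imputation and short-horizon forecasting for
longitudinal biomarkers monitored on irregular real-world schedules.

Given per-patient raw biomarker measurements, pharmacy dispensation records
and baseline covariates, the package:

1. **simulate** — generates synthetic cohorts with the statistical structure
   the pipeline assumes (decline-to-plateau trajectories, AR(1) wiggle,
   value- and adherence-dependent visit skipping, imperfect refills), since
   real monitoring data of this kind are typically access-restricted;
2. **preprocess** — standardizes raw values across assay formats with a
   log-ratio against format-specific baseline medians and aligns them to a
   90-day grid (nearest observation within a 45-day window; otherwise
   missing);
3. **adherence** — computes interval adherence from dispensation records
   using the availability-with-carry-over convention (CMA9-style), values in
   [0, 1] per 90-day interval;
4. **impute** — fills missing grid cells by interval-specific linear models
   on de-meaned lag/lead values (t−2, t−1, t+1, t+2) plus covariates,
   drawing Gaussian residual noise (or predictive mean matching), sweeping
   forward and iterating through a burn-in phase (default 15), then
   branching into m = 10 completed datasets;
5. **forecast** — trains a gradient-boosted tree ensemble and a small
   recurrent network to predict the value 1 and 2 intervals ahead, under a
   Full-Information feature set and a Skipped-Last-Visit set that withholds
   the previous interval's value; patient-level 80/20 split shared across
   all imputations; bootstrap ensembles provide within-model prediction
   variance;
6. **evaluate** — Rubin's-rules pooling of predictions (Q̄, W, B,
   T = W + (1+1/m)B, df, 95% CI) and of per-imputation RMSEs (delta-method
   within-variance), overall and per time point.

## CLI

```sh
# end-to-end on a synthetic cohort
trajimpute --seed 7 --workdir out run-all

# or stage by stage
trajimpute --seed 7 --workdir out simulate
trajimpute --seed 7 --workdir out preprocess
trajimpute --seed 7 --workdir out adherence
trajimpute --seed 7 --workdir out impute
trajimpute --seed 7 --workdir out forecast
trajimpute --seed 7 --workdir out evaluate

# validate any interchange CSV against its schema
trajimpute validate out/adherence.csv adherence
```

Options can also come from a flat YAML config (`--config cfg.yaml`); see
`trajimpute.config.PipelineConfig` for all keys and defaults (grid_days=90,
match_window_days=45, burnin=15, m=10, train_fraction=0.8, log base
natural or base10, learner sizes, ...). Unknown keys are rejected.

File schemas (CSV with header, missing = empty field, days are integer
days since diagnosis):

- `measurements.csv` — patient_id, day, raw_value, assay_format
- `treatment.csv` — patient_id, treatment_start_day
- `dispensations.csv` — patient_id, fill_day, days_supplied
- `covariates.csv` — patient_id, age_at_dx, bmi, sex, first_line_treatment
- outputs: `aligned.csv`, `adherence.csv`, `imputed.csv`,
  `impute_trace.csv`, `predictions.csv`, `pooled_predictions.csv`,
  `rmse_report.csv`, `summary.json`, plus a `manifest.json` chaining
  content hashes across stages.

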
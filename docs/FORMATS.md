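# File formats

All files are headered UTF-8 CSV with ISO-8601 dates, or JSON.

## Inputs (written by `steppath simulate`, or user-supplied, same schema)

| file | columns |
|---|---|
| `steps.csv` | `person_id, date, steps, wear_minutes` — one row per person-day |
| `bmi.csv` | `person_id, date, bmi` — EHR-style BMI measurements |
| `genetics.csv` | `person_id, score, pc1..pc10` — polygenic score + PCs |
| `dosages.csv` | `person_id, snp_0..snp_K` — allele dosages in [0, 2] (optional; score can be computed from these with `snp_weights.csv`) |
| `snp_weights.csv` | `snp_id, weight` |
| `covariates.csv` | `person_id, age, sex, cancer, cad, sbp, alcohol, education, smoking, baseline_bmi` — blanks are missing |
| `truth.json` | generator config + per-person true PRS and latent onset times |

`sex` is `female`/`male`; `education` is `college`/`some_college`/`no_college`;
binary conditions are 0/1.

## Curation outputs (`steppath curate`)

* `analytic_cohort.csv` — `person_id, t0, baseline_bmi, baseline_steps,
  event, time` plus merged covariates (`age` renamed `baseline_age`).
  `time` is years from `t0` (first valid monitoring day).
* `exposure.csv` — `person_id, month, month_index, mean_steps,
  n_valid_days, first_valid_date, t_start, t_stop`.
* `attrition.json` — per-rule person counts, per-person exclusion reasons,
  and the day-level filter audit.

## Model outputs

* `scores.csv` (`steppath score`) — `person_id, raw_score, prs_residual,
  percentile`.
* `fit.json` (`steppath fit`) — pooled coefficients, covariance, term map,
  model spec (terms, knots, interaction), imputation report, interaction
  chunk test; round-trips through `steppath.pipeline.fit_from_dict`.
* `targets.csv` (`steppath invert`) — `prs_percentile,
  baseline_bmi_stratum, steps_at_unit_hr, ci_low, ci_high, flags`.
  Empty cells mean no crossing of HR = 1.00 in the observed step range;
  `flags` explains (`one_sided_interval`, `unattainable_in_range`,
  `multiple_crossings`).
* `incidence.csv` (`steppath incidence`) — `prs_percentile, steps, year,
  risk, ci_low, ci_high` with risks as probabilities in [0, 1].
* `summary.txt`, `manifest.json` (`steppath run`) — the plain-text report
  and the reproducibility manifest (versions, seed, config hash).
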
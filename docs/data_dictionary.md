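# Column dictionary

All tables are comma-separated text with a header row. Times are days
unless the column says months (1 month = 30.44 days).

## Patient tables (`control_patients.csv`, `treated_patients.csv`)

| column | type | meaning |
|---|---|---|
| patient_id | str | unique id, prefix C (control) / T (treated) |
| cohort | str | `control` or `treated` |
| age | years | age at treatment start |
| sex_female | 0/1 | 1 = female |
| onset_bulbar | 0/1 | 1 = bulbar symptom onset, 0 = limb |
| baseline_alsfrs | 0-48 | ALSFRS-R at treatment start |
| latency_days | days | symptom onset to treatment start |
| riluzole | 0/1 | riluzole use |
| survival_days | days | min(event time, censoring horizon), from treatment start |
| event | 0/1 | 1 = death observed, 0 = administratively censored |

## Visits (`visits.csv`)

patient_id, cohort, month (visit month from treatment start), alsfrs
(ALSFRS-R total, 0-48). Visits stop strictly before death/censoring.

## Biomarkers (`biomarkers.csv`, long format)

patient_id, package (`imaging` | `cytokines` | `hematology`), month,
variable, value (standardized units; ordinal variables carry bin codes).
Missing entries are absent values.

## Generator truth (`truth_latent_responder.csv`)

patient_id, latent_responder (0/1). Written for evaluation only; no
analysis stage reads it.

## Stage outputs

* `km_summary.csv` — cohort, n, median_days, median CI bounds.
* `survival_fits.csv` — model (`cox` / `exponential_ph` / `weibull_aft`),
  term, coef, se, wald_chisq, p, hazard_ratio or event_time_ratio.
* `survival_tests.csv` — log-rank and Wilcoxon statistic + p.
* `matched_sets.csv` — treated_id, rank (1..k), control_id, Mahalanobis
  distance.
* `matched_tost.csv` — covariate, margin, both one-sided p values,
  equivalent flag, degenerate flag.
* `matched_bootstrap.csv` — draws, mean-of-medians per arm, median and
  range of per-draw YP p.
* `matched_bootstrap_draws.csv` — per-draw KM medians and YP p (thinned
  above 1,000 draws).
* `decline_coefficients.csv` / `decline_summary.csv` /
  `decline_predicted.csv` — mixed-model estimates, the interaction test and
  evaluated group difference, and the predicted mean trajectory grid.
* `responder_glm.csv` — term, coef_per_day (rate scale), se.
* `responder_labels.csv` — patient_id, predicted_days, observed_days,
  censored, residual_days, label.
* `responder_waterfall.csv` — the same rows sorted by descending residual.
* `control_residuals.csv` — per-control predicted/observed/residual.
* `responder_summary.csv` — label counts, tests, training diagnostics.
* `signature_cytokine_auc.csv` — variable, group-test p, p<0.1 flag.
* `signature_pc_tests.csv` — timepoint, pc, p, significance, retained
  variable count after the |loading| > 0.5 threshold.
* `signature_summary.csv` — timepoint, number of significant PCs, meta-PC
  ROC AUC and permutation p.
* `manifest.json` — config, per-stage seeds, SHA-256 per artifact.
* `run_log.jsonl` — one JSON line per completed stage (seed + hashes).
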
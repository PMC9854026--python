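# vbacval

Scoring and external-validation toolkit for the Grobman vaginal-birth-after-
caesarean (VBAC) prediction nomograms, aimed at obstetric epidemiologists and
biostatisticians who counsel women with one prior lower-segment caesarean
about a trial of labour (TOLAC).

A TOLAC ends either in a successful vaginal birth (VBAC) or in an emergency
repeat caesarean, and the probability of success is the central quantity of
the counselling conversation. The two most widely used prediction rules are
fixed-coefficient logistic nomograms:

- **antenatal model** (usable from the booking visit):

  `w = 3.766 − 0.039·age − 0.060·BMI + 0.888·I(prior vaginal delivery) +
  1.003·I(prior VBAC) − 0.632·I(recurring caesarean indication)`

- **intrapartum model** (adds the admission examination):

  `w = 7.059 − 0.037·age − 0.044·BMI + 0.955·I(prior VD) + 0.851·I(prior
  VBAC) − 0.655·I(recurring) − 0.109·GA − 0.499·I(hypertensive disease) +
  0.044·effacement(%) + 0.109·dilation(cm) + 0.082·station −
  0.452·I(induction)`

with predicted success probability `p = exp(w) / (1 + exp(w))`.

`vbacval` applies these equations to patient-level cohorts and runs the full
external-validation battery a registry study reports:

- **Calibration** — fixed probability-decile tables (0–10 %, 11–20 %, …,
  91–100 %) of observed vs mean predicted VBAC proportion with Wilson (or
  unclipped Wald) binomial intervals, and the Hosmer–Lemeshow grouped
  chi-square (fixed-decile or classic equal-count grouping; development
  `G−2` or validation `G` degrees of freedom).
- **Discrimination** — ROC curve over all score thresholds (positive class
  VBAC), trapezoidal AUC with DeLong or Hanley–McNeil confidence intervals.
- **Cohort description** — per-variable VBAC-vs-ERCS association tables:
  uncorrected Pearson chi-square for categorical predictors, Mann–Whitney U
  with mean ranks or the pooled t-test for continuous ones.
- **Synthetic cohorts** — a generator that emulates a Jordanian TOLAC
  registry's covariate margins, with a calibration-drift outcome model
  `P(VBAC) = logistic(α + β·w)` and a counselling-selection mechanism
  `P(retain) = logistic(γ·(p − m))`, so every pipeline stage is testable
  without restricted hospital data.

## Worked example

Simulate a registry-sized antenatal cohort and validate the antenatal model
on it:

```sh
vbacval simulate --variant antenatal --n 714 --seed 7 --out cohort.csv
vbacval report --model antenatal --in cohort.csv --out-dir results
```

`results/summary.json` (seed 7) contains:

```json
{
  "auc": 0.644,
  "auc_ci": [0.5888, 0.6992],
  "hl_statistic": 18.3704,
  "hl_df": 5,
  "hl_p": 0.0025,
  "mean_predicted_percent": 82.02,
  "sd_predicted_percent": 13.01,
  "prevalence_percent": 83.75,
  "n_complete_cases": 714
}
```

Reading: 83.75 % of the simulated women achieved a VBAC; the mean predicted
success probability was 82.0 ± 13.0 %, and the model ranked successes above
failures with AUC 0.64 (95 % CI 0.59–0.70). The low Hosmer–Lemeshow p-value
reflects the generator's deliberate calibration drift (its default slope is
attenuated below 1 to reproduce a realistically modest AUC; see
`docs/methods.md`). The accompanying `calibration.tsv` shows the familiar
registry pattern — the top two deciles hold two-thirds of the cohort:

```text
label    n    attended_vb  observed_probability  mean_predicted
81-90    194  169          87.11                 85.65
91-100   278  248          89.21                 93.30
```

Other entry points: `vbacval score` appends `linear_predictor` and
`probability_percent` columns to a cohort CSV, `vbacval describe` writes the
association table, `vbacval chisq` tests a contingency TSV, and
`vbacval coefficients` dumps the coefficient registry as JSON. Cohort files
are RFC-4180 CSV with a header; canonical columns are the record field names
(`age, bmi_booking, prior_vaginal_delivery, prior_vbac,
recurring_indication, htn_status, outcome`, plus `bmi_last_visit,
gestational_age, htn_flag, effacement, dilation, station, induction` for
intrapartum data). Booleans are written 0/1 and accepted as
0/1/yes/no/true/false; missing values are empty cells ("NA" accepted on
read). Non-canonical headers bind via `--map field=column`.

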
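# Methods

## Scoring model

Both nomograms are fixed-coefficient logistic scores: a linear predictor
`w` over the patient's covariates followed by `p = exp(w)/(1+exp(w))`.
The coefficients are carried as data (`CoefficientSet` registry), not
inlined arithmetic, so the antenatal and intrapartum models share one
evaluation engine and perturbed sets can be injected (the synthetic
generator's calibration machinery and several tests rely on this). No
refitting of coefficients is performed anywhere; the package is strictly an
application-and-validation tool.

Two modelling choices deserve emphasis:

- **Effacement scale.** Cervical effacement enters the intrapartum score on
  the raw 0–100 percent scale with weight 0.044 per percentage point, i.e.
  the effacement term alone spans 0–4.4 on the log-odds scale and dominates
  the score. This follows the published equation literally. Some
  presentations of the original model use other scalings; users whose data
  encode effacement differently must rescale before mapping the column,
  because results are very sensitive to this unit.
- **Vaginal-birth history.** The equations carry two separate indicators:
  any prior vaginal delivery, and prior VBAC specifically. Registry tables
  often report the three mutually exclusive histories (none / vaginal birth
  before the caesarean / prior VBAC). The record type keeps the two flags
  independent; the generator maps the categories as none → (0,0), VB before
  CS → (1,0), prior VBAC → (1,1), on the reading that a VBAC is itself a
  vaginal delivery so both terms apply. Whether the original model intended
  the flags to overlap this way is not decidable from the published
  equation text; the mapping is therefore documented rather than enforced
  on user data.
- **BMI binding.** The antenatal model reads `bmi_booking` and the
  intrapartum model `bmi_last_visit`, with no silent fallback: the source
  equations name "pre-pregnancy"/"booking" BMI antenatally and
  last-antenatal-visit BMI intrapartum, and the two can differ materially
  in late pregnancy. Users decide which of their columns to bind.
- The original model's race term is omitted entirely (no placeholder
  coefficient), matching how the model is applied outside the population it
  was developed in.

Numerics: the logistic transform uses `scipy.special.expit` and clamps to
the open interval (0, 1) at float64 resolution, so extreme but valid
covariates never produce a degenerate 0/1 probability. Scoring is pure:
identical records give bit-identical results.

## Validation statistics

**Calibration table.** Predicted probabilities (percent) are assigned to
ten *fixed* ranges 0–10, 11–20, …, 91–100 — not equal-count deciles. The
printed labels are read as half-open intervals on the continuous scale:
bin 1 is [0, 10] and bin k ≥ 2 is (10(k−1), 10k], so exactly 10.0 % falls
in "0–10" and 10.0001 % in "11–20". Empty bins are reported with n = 0 and
NA intervals. Binomial intervals default to Wilson (always inside
[0, 100]); the Wald interval is offered unclipped because registry reports
computed this way can print bounds outside [0, 100], and reproducing that
behaviour is occasionally needed when cross-reading such tables.

**Hosmer–Lemeshow.** `H = Σ_g (O_g − E_g)² / (E_g (1 − E_g/n_g))` over
non-empty groups, with `E_g` the summed predicted probabilities. Grouping
defaults to the same fixed deciles as the calibration table (so the H–L
groups match it row for row); the classic equal-count grouping is a flag.
Degrees of freedom: `G − 2` by default (the SPSS/model-development
convention most registry reports quote), with a `validation` policy using
`G`. When predictions are *fixed externally* rather than fitted to the data
at hand, each group contributes an approximately chi-square(1) term, so `G`
is the statistically appropriate reference distribution — the Monte-Carlo
calibration check below uses it; with `G − 2` the same simulation rejects a
perfectly calibrated design at ~13 % instead of ~5 %. `G = 2` with the
development policy yields df 0, treated as the chi-square point mass at
zero. A group with degenerate variance (`E_g` = 0 or `n_g`) contributes 0
when observed matches expected exactly and is an error otherwise.

**ROC/AUC.** Thresholds sweep the distinct observed scores with the rule
"predict VBAC when score ≥ threshold", ties grouped, endpoints (0,0) and
(1,1) appended; AUC is the trapezoidal area, which equals the Mann–Whitney
concordance probability with ties counted ½ (a brute-force all-pairs oracle
asserts this identity in the tests). Confidence intervals: DeLong's
structural-components variance by default, Hanley–McNeil as the lightweight
alternative; intervals are clipped to [0, 1] and flagged undefined with
fewer than two observations in either class.

**Association tables.** Categorical predictors: uncorrected Pearson
chi-square, even for 2×2 tables — registry reports of this kind print
uncorrected statistics, and the package matches them; expected counts
below 5 are flagged rather than corrected. Continuous predictors:
Mann–Whitney U (midrank ties, tie-corrected normal approximation without
continuity correction — the large-sample/SPSS form; exact enumeration
available as a small-sample oracle) or the pooled-variance t-test. The
per-variable test assignment is configurable; the defaults rank-test age
antenatally but t-test it intrapartum, mirroring the registry convention
this package is built around. Station, effacement and dilation are grouped
into their reporting bins (−3 / −2 / −1 and 0 / +1 and +2; 0–30 / 40–50 /
60–70 / ≥80 %; closed / 1–2 / 3–4 / ≥5 cm) at report time only — records
keep raw values. Values falling between printed bin labels (e.g.
effacement 55 %) join the nearest lower bin boundary's group, so the four
groups partition the full range. All percentages are column percentages
within outcome group.

## Synthetic cohort generator

The generator emulates a single-centre Jordanian TOLAC registry (term,
singleton, cephalic, one prior lower-segment caesarean; n = 714 antenatal /
697 intrapartum complete cases) at the level of *marginal* distributions:

| margin | default | source |
|---|---|---|
| age | truncated normal 31.96 ± 4.72 on [20, 45] | registry mean/SD/range |
| BMI | truncated normal 29.36 ± 3.64 on [19, 42] (intrapartum: SD 4.63 on [19.5, 42]) | registry mean/SD/range per variant |
| history (none / VB before CS / prior VBAC) | 218:148:348 of 714 | registry category counts |
| hypertension (none / preeclampsia / chronic) | 688:22:4 of 714 | registry category counts |
| induction | 88 of 697 | registry counts |
| effacement bins (0–30/40–50/60–70/≥80) | 57:200:124:316 of 697 | registry counts |
| dilation bins (closed/1–2/3–4/≥5) | 3:76:329:289 of 697 | registry counts |
| station bins (−3/−2/−1,0/+1,+2) | 416:137:134:10 of 697 | registry counts |
| recurring indication | 0.25 | not reported; a typical share of prior caesareans for failure to progress in comparable registries |
| gestational age | truncated normal 39.0 ± 1.0 on [37, 42] | not reported beyond term-only inclusion; a realistic term distribution |

Covariates are drawn **independently** — the registry reports only margins,
and inventing a correlation structure would manufacture structure the data
source does not support. Within each reported admission-finding bin, a
concrete recordable value is drawn uniformly (e.g. effacement 40/45/50
within the 40–50 % bin). The reported intrapartum BMI SD (4.63) differs
from the antenatal one (3.64) at an identical mean; both are kept as
variant-specific defaults rather than reconciled.

**Outcome model.** Each woman's outcome is Bernoulli with
`P(VBAC) = logistic(α + β·w)`, `w` her Grobman linear predictor. `(α, β) =
(0, 1)` is a perfectly calibrated population. The *defaults* were fixed
once so the generated population reproduces the registry's observed
prevalence (~0.83) and discrimination (AUC ~0.65 antenatal / 0.64
intrapartum): antenatal `α = 0.76, β = 0.58`; intrapartum `α = 0.16,
β = 0.34`. Two consequences worth understanding:

- Because covariates are drawn independently at the full registry spread, a
  slope of 1 would yield AUC ≈ 0.74 (antenatal); matching the registry's
  modest AUC therefore *requires* β < 1, and an attenuated slope is
  exactly a calibration drift. The default cohorts hence fail the
  Hosmer–Lemeshow test at registry size even though their overall
  prevalence matches — the generator reproduces the registry's prevalence
  and AUC, not its near-perfect H–L p-value; H–L operating characteristics
  are validated separately under the `(0, 1)` calibrated design.
- The mean *predicted* probability is a function of the covariate margins
  and the literal equations alone, untouched by α/β. Antenatally it lands
  near the registry's 79.5 ± 13.5 %; intrapartum, the literal percent-scale
  effacement term pushes it to ~96 %, far above the registry's printed
  78.6 % — an internal tension of the source report (its printed margins
  and its printed mean prediction are not simultaneously consistent with
  the literal equation) that the package surfaces rather than hides.

**Counselling selection.** Clinicians who support TOLAC mainly for women
with high predicted success crowd the realised cohort into the top
probability deciles. Modelled as independent retention with probability
`logistic(γ·(p − m))`: γ = 0 retains everyone with probability ½ (off by
default, and not applied unless requested); γ ≈ 40 with m = 0.8 puts >90 %
of the retained cohort in the top two deciles. Selection of this kind
*reduces* the measurable AUC of the retained cohort (range restriction),
which is the mechanism's point — it is checked as a directional Monte-Carlo
property.

**Reproducibility.** The seed feeds a root `SeedSequence`; one child stream
per covariate is spawned in a fixed order, record *i* consuming exactly the
*i*-th draw (or *i*-th row of a two-column block where a bin and a
within-bin value are both needed). Growing `n` therefore extends a cohort
without reshuffling earlier records. Truncated normals are inverse-CDF
transforms of uniforms for the same reason. Replicate seeds are derived as
`SeedSequence([root_seed, replicate]) mod 2^31`.

**Parameter recovery.** `parameter_recovery_study` refits
`outcome ~ w` by single-covariate logistic maximum likelihood (statsmodels
Logit, Newton, tolerance 1e−8, ≤100 iterations) on fresh replicates and
reports the spread of the recovered (α, β). It is a validation harness for
the generator — evidence that the simulated calibration drift is the drift
claimed — not a pipeline stage.

## What the synthetic cohorts do and do not show

Passing tests on generated cohorts demonstrate that the scoring engine,
calibration/discrimination statistics and reporting pipeline are correct
and internally consistent under a population with the registry's margins,
prevalence and AUC. They cannot demonstrate properties that depend on the
registry's *joint* covariate distribution (real age–parity–BMI
correlations), its missingness mechanism (the generator produces complete
records; missingness in tests is injected), temporal trends, or neonatal
outcomes — all outside scope.

## Problem sizes

Monte-Carlo checks are sized for precision at interactive cost: the
Hosmer–Lemeshow type-I error uses 200 replicates of n = 5000 calibrated
cohorts; slope recovery 50 replicates of n = 5000; the AUC-concordance
identity is exercised on cohorts up to n = 200 against an O(n²) all-pairs
oracle; margin convergence at n = 10 000 within 3 binomial SDs. The whole
suite runs in well under a minute.

## Known limitations

- The package validates the printed equations; it cannot arbitrate between
  variant effacement scalings or BMI definitions in other publications of
  the same models.
- Wald intervals are deliberately unclipped; consumers wanting guaranteed
  [0, 100] bounds should keep the Wilson default.
- The H–L p-value is convention-dependent (df `G−2` vs `G`); both are
  exposed and the choice is always recorded in the result object.
- No imputation: the inclusion rule is complete-case, as in the registry
  analyses this package mirrors.
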
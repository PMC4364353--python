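# Methods

## Setting and purpose

The package implements the full analysis pipeline of a cross-sectional
cardiovascular-risk study in an HIV cohort on antiretroviral therapy (ART):
four per-patient CVD risk equations, three guideline statin-eligibility
classifiers, the clinical variable definitions, the agreement statistics
that compare dichotomized scores, and a synthetic-cohort generator that
emulates the study population (n = 254, ages 40–79, 76% male) so that every
stage runs and is testable at desk scale without patient-level data.

## Clinical definitions

Flags are pure functions of one patient record, with the printed operators
kept exactly:

* **Hypertension** — SBP > 140 or DBP > 90 mmHg (> 135/85 in diabetic
  patients), or current antihypertensive medication.
* **Dyslipidemia** — TC > 6.2 mmol/L, HDL < 1.03 mmol/L, or fasting
  TG > 2.26 mmol/L. The operative HDL criterion applies < 1.03 to both
  sexes; a config switch (`hdl_sex_specific`) selects the sex-specific
  dialect (< 1.03 men / < 1.3 women) that some summary tables use.
* **Metabolic syndrome** — at least 3 of 5 modified-NCEP components
  (TG ≥ 1.7; HDL ≤ 1.0 men / ≤ 1.3 women; SBP > 130 or DBP > 85 or on BP
  medication; glucose ≥ 5.6 or diabetes; adiposity). BMI substitutes for
  waist circumference with a configurable threshold, default 28.8 kg/m²
  inclusive — a common waist surrogate. The ≥3-of-5 count is the NCEP
  standard; it is configurable (`mets_min_components`).

Missing values: a flag whose rule cannot be decided from the available
fields raises an indeterminate-flag error; cohort-level exports exclude such
records with a logged count. Canonical units are mmol/L, mmHg, years and
kg/m²; mg/dL input is converted at load (÷38.67 cholesterol, ÷88.57
triglycerides, ÷18.02 glucose), and scores are invariant to the declared
input units to ~1e-10 relative.

## Risk equations

The engines are generic evaluators of (linear predictor, baseline
survival/hazard) forms. Coefficients live only in YAML configs with a
citation string and a SHA-256 checksum that every pipeline run logs; no
coefficient appears in code.

* **Framingham general CVD (10-year)** — sex-specific proportional-hazards
  form `1 − S0^exp(lp − mean_lp)`, lipids in mg/dL internally. The
  transcription is verified against the source's worked example
  (61-year-old female smoker, TC 180, HDL 47, SBP 124 untreated → 10.48%).
* **SCORE (10-year fatal CVD)** — Weibull baseline survival with age as the
  time scale, CHD and non-CHD causes fitted separately:
  `S0(t) = exp(−exp(α)(t−20)^p)`, `S(t) = S0(t)^exp(w)` with
  `w = 0.24·(TC−6) + 0.018·(SBP−120) + 0.71·smoker` (CHD; analogous
  non-CHD terms), ten-year risk `1 − S(age+10)/S(age)` per cause, causes
  summed. High-risk-region baselines are the default (the study setting is
  classified high-risk); the low-risk set ships in the same config.
* **D:A:D (5-year)** — Poisson-rate form `1 − exp(−5·exp(lp))` with
  conventional covariates plus cumulative years of indinavir and
  lopinavir/r exposure and current abacavir/indinavir/lopinavir use — the
  "full" published variant; a reduced-variant slot exists in config but is
  not implemented. The coefficient file carries an explicit provenance
  caveat: slope coefficients are re-keyed as ln(rate ratios) from secondary
  material and the intercept is calibrated so a cohort-median profile has a
  5-year risk near 5%, consistent with the source cohort's event rate. No
  package-level result depends on these values; all quantitative targets
  derive from printed study tables.
* **Pooled Cohort Equations (10-year ASCVD)** — sex/race-stratified log
  terms with interactions, `1 − S0^exp(lp − mean_lp)`; verified against the
  published reference profiles (55-year-old, TC 213 mg/dL, HDL 50, SBP 120
  untreated, nonsmoker → 5.4% / 2.1% / 6.1% / 3.0% across strata). Ages
  outside 40–79 are refused; race "other" scores with the white strata and
  a logged warning (the study cohort is entirely white).

Categories: Framingham < 10% low, [10%, 20%) moderate, ≥ 20% high (the
boundary overlap in the verbal banding is resolved to ≥ 20% high, matching
the eligibility rule "FRS ≥ 20%"); SCORE < 1% / [1%, 5%) / ≥ 5%; DAD high
iff strictly > 5%; ASCVD elevated iff ≥ 7.5%.

A genuine property of the published female Pooled Cohort equation: for
smokers with high TC and low HDL near age 40, d(lp)/d(ln age) is negative,
so risk is locally *decreasing* in age. The property suite therefore
asserts age-monotonicity for Framingham, SCORE, D:A:D and the male PCE
strata only; SBP- and smoking-monotonicity hold for all four models.

## Guideline classifiers

Each classifier returns a verdict plus the first matching rule identifier
(precedence affects reporting only). EACS: CVD, diabetes, or FRS ≥ 20%.
ESC/EAS: CVD, diabetes, TC ≥ 8 mmol/L, SCORE ∈ [5%, 10%) with LDL ≥ 2.5, or
SCORE ≥ 10% with LDL ≥ 1.8 — "between 5 and 10%" is implemented as the
half-open [5%, 10%) so the two SCORE rules partition the axis, and the
guideline's "considered" category is pooled into not-recommended (a config
flag surfaces it for exploratory reports, mapped to SCORE ∈ [1%, 5%) with
LDL ≥ 2.5). ACC/AHA: the four statin-benefit groups, with the LDL window
[1.8, 4.9] mmol/L inclusive at both ends. Eligibility prevalences are
computed on the statin-naive subset with Agresti–Coull intervals.

## Agreement statistics

For two dichotomized scores on the same patients (a = both low, b/c =
discordant, d = both high, n = a+b+c+d):

* observed agreement `(a+d)/n`, CI by Agresti–Coull on (a+d) of n;
* specific agreement, high `2d/(2d+b+c)` and low `2a/(2a+b+c)`, with
  delta-method variances obtained by propagating the multinomial
  covariance of (concordant cell, total discordance) through the ratio;
* Cohen's kappa `(p_o − p_e)/(1 − p_e)` with the Fleiss–Cohen–Everitt
  (1969) asymptotic variance (a percentile-bootstrap alternative is
  provided); verbal bands ≤ 0.20 poor, 0.21–0.40 fair, 0.41–0.60 moderate,
  0.61–0.80 substantial, > 0.80 very good;
* Agresti–Coull interval: `ñ = n + z²`, `p̃ = (x + z²/2)/ñ`, half-width
  `z·√(p̃(1−p̃)/ñ)`, clipped to [0, 1], z = 1.959964 for 95%;
* relative increase `100·(n_new − n_ref)/n_ref` with a paired
  patient-level bootstrap CI (10⁴ resamples by default) when per-patient
  flags are available — paired, because the same people tend to be
  eligible under both rules.

Report rounding is half-up (two decimals for agreement statistics, one for
percentages), matching how statistical packages print.

## Synthetic cohort generator

A Gaussian copula joins one latent normal per variable. Binary variables
are thresholded at their target prevalence; continuous variables transform
the latent through normal or log-normal quantile maps whose free parameters
are solved from printed anchors:

* age — normal truncated to [40, 79]; σ from the printed IQR (44–55), μ
  solved numerically so the *truncated* median is 49;
* BMI — log-normal, median 24.5, σ from Q3 = 27.3 (also yields ~10%
  BMI ≥ 30, close to the printed 11.8% obesity);
* TC — log-normal with median 5.6 mmol/L (not printed; chosen once as
  typical for an ART cohort) and σ solved so P(TC > 6.2) = 35.4% exactly;
* TG — log-normal median 1.9, σ solved so P(TG > 2.26) = 37.8%;
* HDL — sex-specific log-normal (medians 1.25/1.5, σ 0.25), giving the
  printed ~24.8% low-HDL prevalence; HDL is forced below TC;
* LDL — Friedewald-style TC − HDL − TG/2.2 plus noise, clipped;
* glucose — log-normal median 5.3, σ 0.12 (unprinted; the median is the
  calibration dial that places the derived metabolic-syndrome prevalence
  near the published 30.3%); diabetic records draw 7.0 + Exp(1.5);
* ART exposure — duration log-normal (median 6, Q3 10.4, floored at 1
  year per the inclusion criterion); indinavir/lopinavir years are
  zero-inflated exponentials capped at the ART duration.

Blood pressure is drawn branch-wise so the derived hypertension flag hits
its target by construction: treated records (19.3%) and untreated-elevated
records (hypertension 31.5% total) are drawn above the diagnostic
threshold; normotensive records are truncated below it, with the stricter
135/85 cap for diabetic patients. Rare conditions with printed counts —
diabetes 10, prior CVD events 8, statin use 43 at n = 254 — are planted
exactly (the k records with the largest correlated latent), which fixes the
statin-naive subset at 211 every seed; counts scale proportionally at other
n.

Dependence defaults (the study prints no joint distribution; these are the
package's own, config-exposed assumptions): ρ = 0.3 between age and each of
blood pressure, diabetes and prior CVD; between male sex and current
smoking; and between TG and each other metabolic-syndrome component. The
matrix is validated positive semi-definite.

What the generator does *not* emulate: CD4/viral-load structure (no risk
model in scope uses it), longitudinal visits, the joint behaviour of ART
exposure with risk level (e.g. the published ~69.5% abacavir use among
high-DAD patients is emergent here, not calibrated), and any real-data
missingness. Passing calibration tests therefore demonstrates that the
pipeline machinery is correct under the printed marginals, not that the
synthetic joint distribution reproduces the original cohort; score-level
results (kappas ≈ 0.46–0.66, eligibility ≈ 24–42% on default seeds) are
qualitatively, not numerically, comparable to the published ones.

## Numerical choices and test sizes

Strict-versus-inclusive comparisons follow the printed operators everywhere
(e.g. hypertension > 140, DAD high > 5%, FRS eligibility ≥ 20%, TC ≥ 8,
LDL window inclusive). Quantiles in summary tables use linear (type-7)
interpolation, stated because the study does not name a convention.
Degenerate inputs raise typed errors: empty subsets, zero agreement
denominators, kappa with unanimous marginals.

Calibration tests use n = 10⁴ draws (marginals within ±2 points) and 30–100
study-size draws for seed-averaged checks; the risk-engine property suite
uses 10³ generator records; bootstrap-coverage checks use 500 replicates of
n = 211 with 10³ resamples each. These sizes keep the whole suite under a
minute while leaving Monte-Carlo noise well inside the asserted tolerances.

## Known limitations

* D:A:D coefficient provenance as described above — structurally faithful,
  values to be re-verified against the primary table before clinical use.
* The published summary of current abacavir use is internally inconsistent
  between tables (column shift in one row); the generator follows the
  consistent 138/254 = 54.3% figure.
* Guideline-versus-guideline kappas from the original data (0.61/0.71/0.71)
  require the undeposited patient-level data; the operations that compute
  them are implemented and tested on planted cohorts instead.
* The exact method behind the published CI for the 77.8% relative increase
  is unstated; the paired bootstrap is this package's documented choice and
  its interval (roughly 44–105% on planted flags) is wider than the
  published (63.6–87.6%).
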
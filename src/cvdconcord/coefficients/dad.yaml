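# D:A:D 5-year cardiovascular disease risk equation, "full" model variant:
# conventional risk factors plus HIV-treatment terms (cumulative years of
# indinavir and lopinavir/r exposure; current use of abacavir, indinavir,
# and lopinavir/r).  Poisson-rate form:
#   rate   = exp(intercept + lp)     events per person-year
#   risk5  = 1 - exp(-5 * rate)
# Lipids in mmol/L, SBP in mmHg, age and exposures in years.
model_id: dad
source_citation: >
  Friis-Moller N et al. Predicting the risk of cardiovascular disease in
  HIV-infected patients: the D:A:D study. Eur J Cardiovasc Prev Rehabil
  2010;17:491-501 (full model).
notes: >
  PROVENANCE CAVEAT: the primary coefficient table was not available for
  byte-level verification when this file was prepared.  Slope coefficients
  are re-keyed as ln(rate ratios) of the published full model from
  secondary material, and the intercept is calibrated so that a
  cohort-median risk profile (49-year-old male smoker on abacavir,
  TC 5.5, HDL 1.2 mmol/L, SBP 125) has a 5-year risk near 5%, matching the
  source cohort's event rate.  Re-verify against the primary publication
  before any clinical use.  Package-level results do not depend on these
  values; all quantitative targets use the printed study tables.
strata:
  all:
    intercept: -12.31
    coefficients:
      age: 0.0775
      male: 0.600
      smoker_current: 0.871
      smoker_ex: 0.231
      family_history: 0.405
      diabetes: 0.642
      total_chol: 0.231
      hdl: -0.616
      sbp: 0.011
      years_indinavir: 0.058
      years_lopinavir: 0.068
      current_abacavir: 0.519
      current_indinavir: 0.095
      current_lopinavir: 0.095
variants:
  reduced: null  # slot reserved; not implemented
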
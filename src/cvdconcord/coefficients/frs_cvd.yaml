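# Framingham general cardiovascular disease risk profile, 10-year horizon.
# Sex-specific Cox proportional-hazards form:
#   risk = 1 - S0 ^ exp(lp - mean_lp)
# Continuous predictors enter as natural logs; lipids in mg/dL, SBP in mmHg.
# The SBP term uses the treated coefficient when the patient takes
# antihypertensive medication and the untreated coefficient otherwise.
model_id: frs_cvd
source_citation: >
  D'Agostino RB Sr et al. General cardiovascular risk profile for use in
  primary care: the Framingham Heart Study. Circulation 2008;117:743-53.
  Coefficients from the published sex-specific models (Table 2 of the
  source); verified against the source's worked example (61-year-old woman,
  TC 180 mg/dL, HDL 47, SBP 124 untreated, smoker: 10-year risk 10.48%).
notes: validated age range 30-74 years; use outside it warns.
strata:
  male:
    coefficients:
      ln_age: 3.06117
      ln_total_chol: 1.12370
      ln_hdl: -0.93263
      ln_sbp_untreated: 1.93303
      ln_sbp_treated: 1.99881
      smoker: 0.65451
      diabetes: 0.57367
    mean_lp: 23.9802
    baseline_survival: 0.88936
  female:
    coefficients:
      ln_age: 2.32888
      ln_total_chol: 1.20904
      ln_hdl: -0.70833
      ln_sbp_untreated: 2.76157
      ln_sbp_treated: 2.82263
      smoker: 0.52873
      diabetes: 0.69154
    mean_lp: 26.1931
    baseline_survival: 0.95012
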
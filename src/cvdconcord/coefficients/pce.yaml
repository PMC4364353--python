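# Pooled Cohort Equations: 10-year atherosclerotic CVD risk, sex/race strata.
#   risk = 1 - S0 ^ exp(lp - mean_lp)
# Continuous predictors enter as natural logs with stratum-specific
# interactions; lipids in mg/dL, SBP in mmHg.  Validated for ages 40-79.
model_id: pce
source_citation: >
  Goff DC Jr et al. 2013 ACC/AHA Guideline on the Assessment of
  Cardiovascular Risk. Circulation 2014;129(25 Suppl 2):S49-73.
  Coefficients, centering means, and baseline survivals from the published
  equation appendix (Appendix 7, Table A).
notes: >
  Patients of race "other" are scored with the white strata (logged
  warning), following the guideline's own instruction.
strata:
  white_female:
    coefficients:
      ln_age: -29.799
      ln_age_sq: 4.884
      ln_total_chol: 13.540
      ln_age_x_ln_total_chol: -3.114
      ln_hdl: -13.578
      ln_age_x_ln_hdl: 3.149
      ln_sbp_treated: 2.019
      ln_sbp_untreated: 1.957
      smoker: 7.574
      ln_age_x_smoker: -1.665
      diabetes: 0.661
    mean_lp: -29.18
    baseline_survival: 0.9665
  black_female:
    coefficients:
      ln_age: 17.114
      ln_total_chol: 0.940
      ln_hdl: -18.920
      ln_age_x_ln_hdl: 4.475
      ln_sbp_treated: 29.291
      ln_age_x_ln_sbp_treated: -6.432
      ln_sbp_untreated: 27.820
      ln_age_x_ln_sbp_untreated: -6.087
      smoker: 0.691
      diabetes: 0.874
    mean_lp: 86.61
    baseline_survival: 0.9533
  white_male:
    coefficients:
      ln_age: 12.344
      ln_total_chol: 11.853
      ln_age_x_ln_total_chol: -2.664
      ln_hdl: -7.990
      ln_age_x_ln_hdl: 1.769
      ln_sbp_treated: 1.797
      ln_sbp_untreated: 1.764
      smoker: 7.837
      ln_age_x_smoker: -1.795
      diabetes: 0.658
    mean_lp: 61.18
    baseline_survival: 0.9144
  black_male:
    coefficients:
      ln_age: 2.469
      ln_total_chol: 0.302
      ln_hdl: -0.307
      ln_sbp_treated: 1.916
      ln_sbp_untreated: 1.809
      smoker: 0.549
      diabetes: 0.645
    mean_lp: 19.54
    baseline_survival: 0.8954
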
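# SCORE: 10-year risk of a first fatal atherosclerotic event.
# Weibull baseline survival with age as the time scale, fitted separately
# for coronary heart disease (chd) and non-coronary CVD (non_chd):
#   S0(t)    = exp(-exp(alpha) * (t - 20)^p)
#   S(t)     = S0(t) ^ exp(w),  w = b_chol*(TC - 6) + b_sbp*(SBP - 120) + b_smoker
#   risk10   = 1 - S(age+10)/S(age)  per cause, causes then summed.
# TC in mmol/L, SBP in mmHg.  Separate baseline parameter sets for high-
# and low-risk European regions; the high-risk set is the package default.
model_id: score
source_citation: >
  Conroy RM et al. Estimation of ten-year risk of fatal cardiovascular
  disease in Europe: the SCORE project. Eur Heart J 2003;24:987-1003.
  Weibull shape/scale and risk-factor coefficients from the published
  model tables.
centering:
  total_chol: 6.0
  sbp: 120.0
coefficients:
  chd:
    total_chol: 0.24
    sbp: 0.018
    smoker: 0.71
  non_chd:
    total_chol: 0.02
    sbp: 0.022
    smoker: 0.63
regions:
  high:
    male:
      chd: {alpha: -21.0, p: 4.62}
      non_chd: {alpha: -25.7, p: 5.47}
    female:
      chd: {alpha: -28.7, p: 6.23}
      non_chd: {alpha: -30.0, p: 6.42}
  low:
    male:
      chd: {alpha: -22.1, p: 4.71}
      non_chd: {alpha: -26.7, p: 5.64}
    female:
      chd: {alpha: -29.8, p: 6.36}
      non_chd: {alpha: -31.0, p: 6.62}
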
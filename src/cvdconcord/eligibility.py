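"""Statin-eligibility classifiers for the EACS, ESC/EAS, and ACC/AHA rules.

Each classifier maps one patient plus the relevant risk fraction to a
verdict with the identifier of the first triggering rule, following the
order in which the guidelines list their criteria (precedence affects only
the reported trigger, never the verdict):

* EACS — recommended for established CVD, diabetes, or 10-year
  Framingham CVD risk >= 20%;
* ESC/EAS — recommended for CVD, diabetes, TC >= 8 mmol/L, SCORE in
  [5%, 10%) with LDL >= 2.5 mmol/L, or SCORE >= 10% with LDL >= 1.8 mmol/L
  ("between 5 and 10%" is taken as the half-open [5, 10) so the two SCORE
  rules partition the axis); the guideline's "considered" category is
  pooled into not_recommended by default;
* ACC/AHA — the four statin-benefit groups: clinical CVD; LDL >= 4.9
  mmol/L; diabetes with LDL 1.8-4.9; LDL 1.8-4.9 with 10-year ASCVD risk
  >= 7.5% and neither CVD nor diabetes.  The LDL window is inclusive at
  both ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .agreement import agresti_coull_ci
from .cohort import PatientRecord

Guideline = Literal["eacs", "esc_eas", "acc_aha"]
Verdict = Literal["recommended", "considered", "not_recommended"]

GUIDELINES: tuple[str, ...] = ("eacs", "esc_eas", "acc_aha")


class EligibilityInputError(Exception):
    """A required input for an eligibility rule is missing."""


@dataclass(frozen=True)
class EligibilityDecision:
    """Per-guideline verdict with the identifier of the triggering rule."""

    guideline: Guideline
    verdict: Verdict
    trigger: Optional[str] = None

    def __post_init__(self):
        if self.verdict == "recommended" and not self.trigger:
            raise ValueError("a recommended verdict must name its trigger")


def eacs_decision(p: PatientRecord, frs10: float) -> EligibilityDecision:
    """EACS rule: CVD, diabetes, or Framingham 10-year CVD risk >= 20%."""
    if p.prior_cvd_event:
        trigger = "prior_cvd"
    elif p.diabetes:
        trigger = "diabetes"
    elif frs10 >= 0.20:
        trigger = "frs_ge_20"
    else:
        return EligibilityDecision("eacs", "not_recommended")
    return EligibilityDecision("eacs", "recommended", trigger)


def esc_eas_decision(
    p: PatientRecord, score10: float, surface_considered: bool = False
) -> EligibilityDecision:
    """ESC/EAS rule on SCORE and lipids.

    With ``surface_considered`` the exploratory "considered" verdict is
    emitted for SCORE 1-5% with LDL >= 2.5 mmol/L instead of being pooled
    into not_recommended (the pooled behaviour is the default and is what
    all prevalence computations use).
    """
    if p.prior_cvd_event:
        return EligibilityDecision("esc_eas", "recommended", "prior_cvd")
    if p.diabetes:
        return EligibilityDecision("esc_eas", "recommended", "diabetes")
    if p.total_chol is None:
        raise EligibilityInputError(f"{p.id}: total cholesterol required")
    if p.total_chol >= 8.0:
        return EligibilityDecision("esc_eas", "recommended", "tc_ge_8")
    if p.ldl is None:
        raise EligibilityInputError(f"{p.id}: LDL cholesterol required")
    if 0.05 <= score10 < 0.10 and p.ldl >= 2.5:
        return EligibilityDecision("esc_eas", "recommended", "score_5_10_ldl_ge_2.5")
    if score10 >= 0.10 and p.ldl >= 1.8:
        return EligibilityDecision("esc_eas", "recommended", "score_ge_10_ldl_ge_1.8")
    if surface_considered and 0.01 <= score10 < 0.05 and p.ldl >= 2.5:
        return EligibilityDecision("esc_eas", "considered", "score_1_5_ldl_ge_2.5")
    return EligibilityDecision("esc_eas", "not_recommended")


def acc_aha_decision(p: PatientRecord, ascvd10: float) -> EligibilityDecision:
    """ACC/AHA rule: membership in any of the four statin-benefit groups."""
    if p.prior_cvd_event:
        return EligibilityDecision("acc_aha", "recommended", "prior_cvd")
    if p.ldl is None:
        raise EligibilityInputError(f"{p.id}: LDL cholesterol required")
    if p.ldl >= 4.9:
        return EligibilityDecision("acc_aha", "recommended", "ldl_ge_4.9")
    in_window = 1.8 <= p.ldl <= 4.9
    if p.diabetes and in_window:
        return EligibilityDecision("acc_aha", "recommended", "diabetes_ldl_1.8_4.9")
    if in_window and ascvd10 >= 0.075 and not p.diabetes:
        return EligibilityDecision("acc_aha", "recommended", "ascvd_ge_7.5_ldl_1.8_4.9")
    return EligibilityDecision("acc_aha", "not_recommended")


def decide(
    p: PatientRecord,
    guideline: Guideline,
    *,
    frs10: float | None = None,
    score10: float | None = None,
    ascvd10: float | None = None,
) -> EligibilityDecision:
    """Dispatch to one guideline's classifier, checking its risk input."""
    if guideline == "eacs":
        if frs10 is None:
            raise EligibilityInputError("eacs needs frs10")
        return eacs_decision(p, frs10)
    if guideline == "esc_eas":
        if score10 is None:
            raise EligibilityInputError("esc_eas needs score10")
        return esc_eas_decision(p, score10)
    if guideline == "acc_aha":
        if ascvd10 is None:
            raise EligibilityInputError("acc_aha needs ascvd10")
        return acc_aha_decision(p, ascvd10)
    raise ValueError(f"unknown guideline {guideline!r}")


def eligibility_prevalence(
    decisions: Sequence[EligibilityDecision], conf: float = 0.95
) -> tuple[float, tuple[float, float], int, int]:
    """Recommended fraction with its Agresti-Coull CI.

    "Considered" verdicts count as not recommended, matching the pooling
    used for all reported prevalences.  Returns (proportion, (lo, hi),
    recommended count, subset size).
    """
    n = len(decisions)
    if n == 0:
        raise ValueError("empty eligibility subset")
    x = sum(1 for d in decisions if d.verdict == "recommended")
    return x / n, agresti_coull_ci(x, n, conf), x, n
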
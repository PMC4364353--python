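"""Four cardiovascular risk equations and the study's risk categories.

Each engine is a generic evaluator of a (linear predictor, baseline
survival/hazard) form whose coefficients live in version-controlled YAML
configs under :mod:`cvdconcord.coefficients` — no coefficient appears in
code.  The four models are:

* ``frs_cvd`` — Framingham general-CVD profile, 10-year risk,
  ``1 - S0^exp(lp - mean_lp)`` with sex strata;
* ``score`` — SCORE fatal-CVD equation, Weibull baseline survival with age
  as the time scale, CHD and non-CHD causes computed separately and summed;
  high-risk-region calibration by default;
* ``dad`` — D:A:D 5-year CVD model with HIV-treatment terms,
  ``1 - exp(-5 * exp(lp))``;
* ``pce`` — Pooled Cohort Equations, 10-year ASCVD risk, sex/race strata.

Risk categories follow the study's cut-offs: Framingham <10/10-20/>=20%
(low/moderate/high), SCORE <1/1-5/>=5%, DAD high iff strictly >5%, and
ASCVD elevated iff >=7.5%.
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel

from .cohort import CHOL_MGDL_PER_MMOL, PatientRecord

logger = logging.getLogger(__name__)

ModelId = Literal["frs_cvd", "score", "dad", "pce"]
MODEL_IDS: tuple[str, ...] = ("frs_cvd", "score", "dad", "pce")


class ScoringError(Exception):
    """A record cannot be scored (missing predictor or out-of-range input)."""


class CoefficientConfigError(Exception):
    """A coefficient config file fails schema validation."""


class CoefficientSet(BaseModel):
    """A validated, checksummed coefficient table for one risk model."""

    model_id: str
    source_citation: str
    notes: str = ""
    strata: dict = {}
    coefficients: dict = {}
    regions: dict = {}
    centering: dict = {}
    checksum: str = ""

    model_config = {"extra": "allow"}


_REQUIRED_STRATA = {
    "frs_cvd": ("male", "female"),
    "pce": ("white_male", "white_female", "black_male", "black_female"),
    "dad": ("all",),
}


def load_coefficients(model_id: str, path: str | Path | None = None) -> CoefficientSet:
    """Load and validate a model's coefficient config.

    Without ``path`` the packaged config for ``model_id`` is used.  The
    returned set carries a SHA-256 checksum of the file contents so runs can
    log exactly which coefficient table produced them.
    """
    if model_id not in MODEL_IDS:
        raise CoefficientConfigError(f"unknown model_id {model_id!r}")
    if path is None:
        source = resources.files("cvdconcord.coefficients") / f"{model_id}.yaml"
        raw = source.read_bytes()
    else:
        raw = Path(path).read_bytes()
    data = yaml.safe_load(raw)
    if data.get("model_id") != model_id:
        raise CoefficientConfigError(
            f"config declares model_id {data.get('model_id')!r}, expected {model_id!r}"
        )
    cs = CoefficientSet(**data)
    cs.checksum = hashlib.sha256(raw).hexdigest()
    _validate(cs)
    return cs


def _validate(cs: CoefficientSet) -> None:
    def check_finite(mapping: dict, where: str) -> None:
        for k, v in mapping.items():
            if not math.isfinite(float(v)):
                raise CoefficientConfigError(f"{cs.model_id}:{where}:{k} not finite")

    if cs.model_id == "score":
        if not cs.regions or not cs.coefficients:
            raise CoefficientConfigError("score config needs regions and coefficients")
        for cause in ("chd", "non_chd"):
            check_finite(cs.coefficients[cause], f"coefficients.{cause}")
        for region, sexes in cs.regions.items():
            for sex in ("male", "female"):
                for cause in ("chd", "non_chd"):
                    check_finite(sexes[sex][cause], f"regions.{region}.{sex}.{cause}")
        return
    for name in _REQUIRED_STRATA[cs.model_id]:
        if name not in cs.strata:
            raise CoefficientConfigError(f"{cs.model_id}: missing stratum {name!r}")
        stratum = cs.strata[name]
        check_finite(stratum["coefficients"], name)
        s0 = stratum.get("baseline_survival")
        if s0 is not None and not (0.0 < s0 < 1.0):
            raise CoefficientConfigError(f"{cs.model_id}:{name}: baseline_survival not in (0,1)")


def load_all_coefficients(
    coeff_dir: str | Path | None = None,
) -> dict[str, CoefficientSet]:
    """All four coefficient sets, from a directory of YAMLs or the packaged ones."""
    return {
        m: load_coefficients(
            m, None if coeff_dir is None else Path(coeff_dir) / f"{m}.yaml"
        )
        for m in MODEL_IDS
    }


def _require(p: PatientRecord, *fields: str) -> None:
    for f in fields:
        if getattr(p, f) is None:
            raise ScoringError(f"{p.id}: missing required predictor {f!r}")


def _evaluate(coefficients: dict[str, float], features: dict[str, float], where: str) -> float:
    lp = 0.0
    for name, beta in coefficients.items():
        if name not in features:
            raise CoefficientConfigError(f"{where}: unknown term {name!r}")
        lp += float(beta) * features[name]
    return lp


# ---------------------------------------------------------------------------
# Framingham general CVD


def framingham_cvd_10y(p: PatientRecord, c: CoefficientSet) -> float:
    """10-year general-CVD risk from the sex-specific Framingham profile."""
    _require(p, "sbp", "total_chol", "hdl", "on_bp_meds")
    if not 30 <= p.age <= 74:
        warnings.warn(
            f"{p.id}: age {p.age} outside the Framingham validated range 30-74",
            stacklevel=2,
        )
    stratum = c.strata[p.sex]
    treated = bool(p.on_bp_meds)
    ln_sbp = math.log(p.sbp)
    features = {
        "ln_age": math.log(p.age),
        "ln_total_chol": math.log(p.total_chol * CHOL_MGDL_PER_MMOL),
        "ln_hdl": math.log(p.hdl * CHOL_MGDL_PER_MMOL),
        "ln_sbp_untreated": 0.0 if treated else ln_sbp,
        "ln_sbp_treated": ln_sbp if treated else 0.0,
        "smoker": 1.0 if p.smoking == "current" else 0.0,
        "diabetes": 1.0 if p.diabetes else 0.0,
    }
    lp = _evaluate(stratum["coefficients"], features, f"frs_cvd:{p.sex}")
    risk = 1.0 - stratum["baseline_survival"] ** math.exp(lp - stratum["mean_lp"])
    return min(max(risk, 0.0), 1.0)


# ---------------------------------------------------------------------------
# SCORE


def score_fatal_cvd_10y(
    p: PatientRecord, c: CoefficientSet, region: str = "high"
) -> float:
    """10-year risk of a first fatal atherosclerotic event (SCORE).

    CHD and non-CHD risks are computed separately and summed, per the
    published algorithm.  ``region`` selects the high- or low-risk
    European calibration (high by default, matching the study setting).
    """
    _require(p, "sbp", "total_chol")
    if region not in c.regions:
        raise ScoringError(f"unknown SCORE region {region!r}")
    baseline = c.regions[region][p.sex]
    smoker = 1.0 if p.smoking == "current" else 0.0
    total = 0.0
    for cause in ("chd", "non_chd"):
        b = c.coefficients[cause]
        w = (
            b["total_chol"] * (p.total_chol - c.centering["total_chol"])
            + b["sbp"] * (p.sbp - c.centering["sbp"])
            + b["smoker"] * smoker
        )
        # Weibull time scale starts at age 20; risk accumulates age -> age+10
        a = baseline[cause]
        s_age = math.exp(-math.exp(a["alpha"]) * (p.age - 20.0) ** a["p"])
        s_age10 = math.exp(-math.exp(a["alpha"]) * (p.age + 10.0 - 20.0) ** a["p"])
        s_age, s_age10 = s_age ** math.exp(w), s_age10 ** math.exp(w)
        cause_risk = 1.0 if s_age <= 0.0 else 1.0 - s_age10 / s_age
        total += min(max(cause_risk, 0.0), 1.0)
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# D:A:D


def dad_cvd_5y(p: PatientRecord, c: CoefficientSet) -> float:
    """5-year CVD risk from the D:A:D full model (with ART exposure terms)."""
    _require(p, "sbp", "total_chol", "hdl")
    stratum = c.strata["all"]
    features = {
        "age": float(p.age),
        "male": 1.0 if p.sex == "male" else 0.0,
        "smoker_current": 1.0 if p.smoking == "current" else 0.0,
        "smoker_ex": 1.0 if p.smoking == "ex" else 0.0,
        "family_history": 1.0 if p.family_history_premature_cvd else 0.0,
        "diabetes": 1.0 if p.diabetes else 0.0,
        "total_chol": float(p.total_chol),
        "hdl": float(p.hdl),
        "sbp": float(p.sbp),
        "years_indinavir": float(p.years_indinavir),
        "years_lopinavir": float(p.years_lopinavir),
        "current_abacavir": 1.0 if p.current_abacavir else 0.0,
        "current_indinavir": 1.0 if p.current_indinavir else 0.0,
        "current_lopinavir": 1.0 if p.current_lopinavir else 0.0,
    }
    lp = stratum["intercept"] + _evaluate(stratum["coefficients"], features, "dad:all")
    risk = 1.0 - math.exp(-5.0 * math.exp(lp))
    return min(max(risk, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Pooled Cohort Equations


def pooled_cohort_ascvd_10y(p: PatientRecord, c: CoefficientSet) -> float:
    """10-year ASCVD risk from the Pooled Cohort Equations.

    Refuses ages outside 40-79 (the model's stated range).  Race "other"
    is scored with the white strata, with a logged warning.
    """
    _require(p, "sbp", "total_chol", "hdl", "on_bp_meds")
    if not 40 <= p.age <= 79:
        raise ScoringError(
            f"{p.id}: the Pooled Cohort Equations apply to ages 40-79, got {p.age}"
        )
    race = p.race
    if race == "other":
        logger.warning("%s: race 'other' scored with white-strata coefficients", p.id)
        race = "white"
    stratum = c.strata[f"{race}_{p.sex}"]
    treated = bool(p.on_bp_meds)
    ln_age = math.log(p.age)
    ln_tc = math.log(p.total_chol * CHOL_MGDL_PER_MMOL)
    ln_hdl = math.log(p.hdl * CHOL_MGDL_PER_MMOL)
    ln_sbp = math.log(p.sbp)
    smoker = 1.0 if p.smoking == "current" else 0.0
    features = {
        "ln_age": ln_age,
        "ln_age_sq": ln_age**2,
        "ln_total_chol": ln_tc,
        "ln_age_x_ln_total_chol": ln_age * ln_tc,
        "ln_hdl": ln_hdl,
        "ln_age_x_ln_hdl": ln_age * ln_hdl,
        "ln_sbp_treated": ln_sbp if treated else 0.0,
        "ln_age_x_ln_sbp_treated": ln_age * ln_sbp if treated else 0.0,
        "ln_sbp_untreated": 0.0 if treated else ln_sbp,
        "ln_age_x_ln_sbp_untreated": 0.0 if treated else ln_age * ln_sbp,
        "smoker": smoker,
        "ln_age_x_smoker": ln_age * smoker,
        "diabetes": 1.0 if p.diabetes else 0.0,
    }
    lp = _evaluate(stratum["coefficients"], features, f"pce:{race}_{p.sex}")
    risk = 1.0 - stratum["baseline_survival"] ** math.exp(lp - stratum["mean_lp"])
    return min(max(risk, 0.0), 1.0)


# ---------------------------------------------------------------------------
# categories

RiskCategory = Literal["low", "moderate", "high"]


def _check_fraction(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be a fraction in [0,1], got {x}")


def frs_category(frs10: float) -> RiskCategory:
    """Framingham bands: <10% low, 10-20% moderate, >=20% high."""
    _check_fraction("frs10", frs10)
    return "low" if frs10 < 0.10 else ("moderate" if frs10 < 0.20 else "high")


def score_category(score10: float) -> RiskCategory:
    """SCORE bands: <1% low, 1-5% moderate, >=5% high."""
    _check_fraction("score10", score10)
    return "low" if score10 < 0.01 else ("moderate" if score10 < 0.05 else "high")


def dad_high(dad5: float) -> bool:
    """DAD high risk iff the 5-year risk strictly exceeds 5%."""
    _check_fraction("dad5", dad5)
    return dad5 > 0.05


def ascvd_elevated(ascvd10: float) -> bool:
    """ASCVD elevated iff the 10-year risk is at least 7.5%."""
    _check_fraction("ascvd10", ascvd10)
    return ascvd10 >= 0.075


@dataclass(frozen=True)
class RiskProfile:
    """The four computed risk fractions and their categorizations."""

    frs10: float
    score10: float
    dad5: float
    ascvd10: float
    frs_cat: RiskCategory
    score_cat: RiskCategory
    dad_high: bool
    ascvd_elevated: bool


def categorize_risk(
    frs10: float, score10: float, dad5: float, ascvd10: float
) -> RiskProfile:
    """Bundle the four fractions with their study categories."""
    return RiskProfile(
        frs10=frs10,
        score10=score10,
        dad5=dad5,
        ascvd10=ascvd10,
        frs_cat=frs_category(frs10),
        score_cat=score_category(score10),
        dad_high=dad_high(dad5),
        ascvd_elevated=ascvd_elevated(ascvd10),
    )


def score_patient(
    p: PatientRecord,
    coefficients: dict[str, CoefficientSet],
    score_region: str = "high",
) -> RiskProfile:
    """All four risks and categories for one record."""
    return categorize_risk(
        framingham_cvd_10y(p, coefficients["frs_cvd"]),
        score_fatal_cvd_10y(p, coefficients["score"], region=score_region),
        dad_cvd_5y(p, coefficients["dad"]),
        pooled_cohort_ascvd_10y(p, coefficients["pce"]),
    )
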
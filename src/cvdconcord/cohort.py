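"""Patient data model, cohort CSV I/O, and clinical flag derivation.

This module defines the canonical per-patient record for a cross-sectional
cardiovascular-risk analysis of an HIV cohort on antiretroviral therapy,
together with the deterministic clinical definitions used downstream:

* arterial hypertension — SBP > 140 or DBP > 90 mmHg (> 135/85 in diabetic
  patients), or use of antihypertensive drugs;
* dyslipidemia — total cholesterol > 6.2 mmol/L, HDL < 1.03 mmol/L, or
  fasting triglycerides > 2.26 mmol/L;
* metabolic syndrome — at least 3 of 5 modified-NCEP components, with BMI
  substituting for waist circumference.

Canonical internal units are mmol/L for lipids and glucose, mmHg for blood
pressure, years for durations, and kg/m^2 for BMI.  Inputs declared in
mg/dL are converted at load time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

# mg/dL per mmol/L conversion factors
CHOL_MGDL_PER_MMOL = 38.67
TG_MGDL_PER_MMOL = 88.57
GLUCOSE_MGDL_PER_MMOL = 18.02

#: columns that must be present in a cohort CSV
REQUIRED_COLUMNS = (
    "id", "age", "sex", "smoking", "sbp", "dbp", "on_bp_meds",
    "total_chol", "hdl", "ldl", "triglycerides", "fasting_glucose",
    "diabetes", "prior_cvd_event", "bmi", "on_lipid_lowering",
)

#: columns that default when absent
OPTIONAL_COLUMNS = (
    "race", "family_history_premature_cvd", "years_indinavir",
    "years_lopinavir", "current_abacavir", "current_indinavir",
    "current_lopinavir", "current_pi", "art_duration",
)

_LIPID_FIELDS = ("total_chol", "hdl", "ldl")


class CohortError(Exception):
    """Base class for cohort-level errors."""


class CohortSchemaError(CohortError):
    """The CSV header does not match the cohort schema."""


class EmptyCohortError(CohortError):
    """The cohort file contains no data rows."""


class RowValidationError(CohortError):
    """One or more rows violate record invariants.

    Attributes
    ----------
    failures : list of (row_number, message)
        1-based data-row numbers with the validation message for each.
    """

    def __init__(self, failures: list[tuple[int, str]]):
        self.failures = failures
        lines = "; ".join(f"row {i}: {msg}" for i, msg in failures[:10])
        more = "" if len(failures) <= 10 else f" (+{len(failures) - 10} more)"
        super().__init__(f"{len(failures)} invalid row(s): {lines}{more}")


class IndeterminateFlagError(CohortError):
    """A clinical flag cannot be decided from the available fields."""


class CohortOptions(BaseModel):
    """Configurable dialects of the clinical definitions.

    ``hdl_sex_specific`` switches the dyslipidemia HDL criterion from the
    operative definition (< 1.03 mmol/L for everyone) to the sex-specific
    variant (< 1.03 men / < 1.3 women).  ``bmi_surrogate_threshold`` is the
    adiposity cut-off standing in for waist circumference in the metabolic
    syndrome rule (inclusive: BMI >= threshold counts); 28.8 kg/m^2 is a
    common waist surrogate.  ``mets_min_components`` is the NCEP component
    count, 3 by default.
    """

    hdl_sex_specific: bool = False
    bmi_surrogate_threshold: float = 28.8
    mets_min_components: int = 3
    units: Literal["mmol/L", "mg/dL"] = "mmol/L"


class PatientRecord(BaseModel):
    """One person's demographics, vitals, labs, ART history and flags."""

    id: str
    age: float
    sex: Literal["male", "female"]
    race: Literal["white", "black", "other"] = "white"
    smoking: Literal["current", "ex", "never"]
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    on_bp_meds: Optional[bool] = None
    total_chol: Optional[float] = None
    hdl: Optional[float] = None
    ldl: Optional[float] = None
    triglycerides: Optional[float] = None
    fasting_glucose: Optional[float] = None
    diabetes: bool = False
    prior_cvd_event: bool = False
    family_history_premature_cvd: bool = False
    bmi: Optional[float] = None
    years_indinavir: float = 0.0
    years_lopinavir: float = 0.0
    current_abacavir: bool = False
    current_indinavir: bool = False
    current_lopinavir: bool = False
    current_pi: bool = False
    art_duration: float = 0.0
    on_lipid_lowering: bool = False

    @field_validator(
        "age", "sbp", "dbp", "total_chol", "hdl", "ldl", "triglycerides",
        "fasting_glucose", "bmi", "years_indinavir", "years_lopinavir",
        "art_duration",
    )
    @classmethod
    def _non_negative(cls, v, info):
        if v is not None and v < 0:
            raise ValueError(f"{info.field_name} must be non-negative, got {v}")
        return v

    @model_validator(mode="after")
    def _cross_field(self):
        if self.hdl is not None and self.total_chol is not None:
            if self.hdl >= self.total_chol:
                raise ValueError(
                    f"hdl ({self.hdl}) must be below total_chol ({self.total_chol})"
                )
        for f in ("years_indinavir", "years_lopinavir"):
            if getattr(self, f) > self.art_duration + 1e-9:
                raise ValueError(
                    f"{f} ({getattr(self, f)}) exceeds art_duration ({self.art_duration})"
                )
        return self


@dataclass(frozen=True)
class ClinicalFlags:
    """Derived comorbidity flags for one record (pure function of it)."""

    hypertension: bool
    dyslipidemia: bool
    metabolic_syndrome: bool
    diabetes: bool
    cvd_present: bool


# ---------------------------------------------------------------------------
# flag derivation


def derive_hypertension(p: PatientRecord) -> bool:
    """Arterial hypertension flag.

    True iff SBP > 140 or DBP > 90 mmHg (> 135/85 if diabetic) or the
    patient takes antihypertensive drugs.  Operators are strict, as printed.
    """
    if p.on_bp_meds:
        return True
    if p.sbp is None or p.dbp is None:
        if p.on_bp_meds is None:
            raise IndeterminateFlagError(f"{p.id}: blood pressure and medication unknown")
        raise IndeterminateFlagError(f"{p.id}: blood pressure missing and not on medication")
    sbp_cut, dbp_cut = (135.0, 85.0) if p.diabetes else (140.0, 90.0)
    return p.sbp > sbp_cut or p.dbp > dbp_cut


def derive_dyslipidemia(p: PatientRecord, *, hdl_sex_specific: bool = False) -> bool:
    """Dyslipidemia flag: TC > 6.2, HDL < 1.03 (or sex-specific), or TG > 2.26.

    With ``hdl_sex_specific`` the HDL criterion is < 1.03 mmol/L for men and
    < 1.3 mmol/L for women; the default applies < 1.03 to everyone.
    """
    if p.total_chol is None and p.hdl is None and p.triglycerides is None:
        raise IndeterminateFlagError(f"{p.id}: no lipid panel")
    hdl_cut = (1.3 if p.sex == "female" else 1.03) if hdl_sex_specific else 1.03
    checks = []
    if p.total_chol is not None:
        checks.append(p.total_chol > 6.2)
    if p.hdl is not None:
        checks.append(p.hdl < hdl_cut)
    if p.triglycerides is not None:
        checks.append(p.triglycerides > 2.26)
    return any(checks)


def metabolic_syndrome_components(
    p: PatientRecord, *, bmi_threshold: float = 28.8
) -> list[Optional[bool]]:
    """The five modified-NCEP components as booleans (None = indeterminate).

    Order: triglycerides >= 1.7; low HDL (<= 1.0 men / <= 1.3 women);
    blood pressure (SBP > 130 or DBP > 85 or on medication);
    glucose >= 5.6 or diabetes; BMI >= ``bmi_threshold``.
    """
    tg = None if p.triglycerides is None else p.triglycerides >= 1.7
    hdl_cut = 1.3 if p.sex == "female" else 1.0
    hdl = None if p.hdl is None else p.hdl <= hdl_cut
    if p.on_bp_meds:
        bp: Optional[bool] = True
    elif p.sbp is None or p.dbp is None:
        bp = None
    else:
        bp = p.sbp > 130 or p.dbp > 85
    if p.diabetes:
        glu: Optional[bool] = True
    elif p.fasting_glucose is None:
        glu = None
    else:
        glu = p.fasting_glucose >= 5.6
    adiposity = None if p.bmi is None else p.bmi >= bmi_threshold
    return [tg, hdl, bp, glu, adiposity]


def derive_metabolic_syndrome(
    p: PatientRecord, *, bmi_threshold: float = 28.8, min_components: int = 3
) -> bool:
    """Metabolic syndrome flag: >= ``min_components`` of the 5 NCEP components.

    Raises :class:`IndeterminateFlagError` only when the decision genuinely
    depends on indeterminate components.
    """
    comp = metabolic_syndrome_components(p, bmi_threshold=bmi_threshold)
    n_true = sum(1 for c in comp if c is True)
    n_unknown = sum(1 for c in comp if c is None)
    if n_true >= min_components:
        return True
    if n_true + n_unknown < min_components:
        return False
    raise IndeterminateFlagError(
        f"{p.id}: {n_unknown} metabolic-syndrome component(s) indeterminate"
    )


def derive_flags(p: PatientRecord, options: CohortOptions | None = None) -> ClinicalFlags:
    """All clinical flags for one record (deterministic, context-free)."""
    opt = options or CohortOptions()
    return ClinicalFlags(
        hypertension=derive_hypertension(p),
        dyslipidemia=derive_dyslipidemia(p, hdl_sex_specific=opt.hdl_sex_specific),
        metabolic_syndrome=derive_metabolic_syndrome(
            p,
            bmi_threshold=opt.bmi_surrogate_threshold,
            min_components=opt.mets_min_components,
        ),
        diabetes=p.diabetes,
        cvd_present=p.prior_cvd_event,
    )


# ---------------------------------------------------------------------------
# subsets


def select_agreement_subset(cohort: Sequence[PatientRecord]) -> list[PatientRecord]:
    """Records eligible for the risk-score agreement analysis.

    Keeps non-diabetic records without a prior CVD event and with total
    cholesterol <= 8 mmol/L and LDL <= 4.9 mmol/L; records with missing
    lipids cannot be verified against the caps and are dropped.  Order is
    preserved and the operation is idempotent.
    """
    kept = []
    for p in cohort:
        if p.diabetes or p.prior_cvd_event:
            continue
        if p.total_chol is None or p.ldl is None:
            continue
        if p.total_chol > 8.0 or p.ldl > 4.9:
            continue
        kept.append(p)
    return kept


def select_eligibility_subset(cohort: Sequence[PatientRecord]) -> list[PatientRecord]:
    """Statin-naive records (not currently on lipid-lowering therapy)."""
    return [p for p in cohort if not p.on_lipid_lowering]


# ---------------------------------------------------------------------------
# CSV I/O

_BOOL_COLUMNS = (
    "on_bp_meds", "diabetes", "prior_cvd_event", "family_history_premature_cvd",
    "current_abacavir", "current_indinavir", "current_lopinavir", "current_pi",
    "on_lipid_lowering",
)

_SEX_IN = {"M": "male", "F": "female", "male": "male", "female": "female"}
_SEX_OUT = {"male": "M", "female": "F"}


def _sidecar_units(path: Path) -> Optional[str]:
    sidecar = path.with_suffix(path.suffix + ".units.json")
    if sidecar.exists():
        return json.loads(sidecar.read_text()).get("units")
    return None


def load_cohort(
    path: str | Path,
    options: CohortOptions | None = None,
) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    The header must contain every column in :data:`REQUIRED_COLUMNS`; sex is
    coded M/F, booleans 0/1, smoking current/ex/never.  Units default to the
    canonical mmol/L; ``options.units`` or a ``<file>.units.json`` sidecar
    (``{"units": "mg/dL"}``) declares mg/dL input, converted on load.

    Raises
    ------
    CohortSchemaError, EmptyCohortError, RowValidationError
    """
    path = Path(path)
    opt = options or CohortOptions()
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, dtype={"id": str})
    except pd.errors.EmptyDataError:
        raise EmptyCohortError(f"{path} has no header or data") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(frame) == 0:
        raise EmptyCohortError(f"{path} contains a header but no rows")

    units = _sidecar_units(path) or opt.units
    if units not in ("mmol/L", "mg/dL"):
        raise CohortSchemaError(f"unknown units declaration {units!r}")

    records: list[PatientRecord] = []
    failures: list[tuple[int, str]] = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        try:
            records.append(_row_to_record(row, units))
        except Exception as exc:  # noqa: BLE001 - surfaced with row number
            failures.append((i, str(exc)))
    if failures:
        raise RowValidationError(failures)
    logger.info("loaded %d records from %s (units=%s)", len(records), path, units)
    return records


def _row_to_record(row: dict, units: str) -> PatientRecord:
    data: dict = {}
    for key, value in row.items():
        if key not in PatientRecord.model_fields:
            continue
        if value is None or (isinstance(value, float) and pd.isna(value)):
            continue
        if key == "sex":
            if value not in _SEX_IN:
                raise ValueError(f"unrecognized sex code {value!r}")
            value = _SEX_IN[value]
        elif key in _BOOL_COLUMNS:
            value = bool(int(value))
        data[key] = value
    if units == "mg/dL":
        for f in _LIPID_FIELDS:
            if f in data:
                data[f] = float(data[f]) / CHOL_MGDL_PER_MMOL
        if "triglycerides" in data:
            data["triglycerides"] = float(data["triglycerides"]) / TG_MGDL_PER_MMOL
        if "fasting_glucose" in data:
            data["fasting_glucose"] = float(data["fasting_glucose"]) / GLUCOSE_MGDL_PER_MMOL
    return PatientRecord(**data)


def cohort_to_frame(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in the CSV schema (sex M/F, booleans 0/1)."""
    rows = []
    for p in cohort:
        d = p.model_dump()
        d["sex"] = _SEX_OUT[d["sex"]]
        for c in _BOOL_COLUMNS:
            if d[c] is not None:
                d[c] = int(d[c])
        rows.append(d)
    return pd.DataFrame(rows)


def write_cohort(cohort: Iterable[PatientRecord], path: str | Path) -> None:
    """Write a cohort CSV readable by :func:`load_cohort`."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def flags_frame(
    cohort: Sequence[PatientRecord], options: CohortOptions | None = None
) -> pd.DataFrame:
    """Per-record derived flags; indeterminate flags become NA with a logged count.

    Returns the input columns augmented with the five flag columns.
    """
    base = cohort_to_frame(cohort)
    n_indeterminate = 0
    cols: dict[str, list] = {
        k: [] for k in ("hypertension", "dyslipidemia", "metabolic_syndrome",
                        "diabetes_flag", "cvd_present")
    }
    for p in cohort:
        try:
            f = derive_flags(p, options)
            cols["hypertension"].append(int(f.hypertension))
            cols["dyslipidemia"].append(int(f.dyslipidemia))
            cols["metabolic_syndrome"].append(int(f.metabolic_syndrome))
            cols["diabetes_flag"].append(int(f.diabetes))
            cols["cvd_present"].append(int(f.cvd_present))
        except IndeterminateFlagError:
            n_indeterminate += 1
            for k in cols:
                cols[k].append(pd.NA)
    if n_indeterminate:
        logger.warning("%d record(s) with indeterminate flags excluded", n_indeterminate)
    for k, v in cols.items():
        base[k] = v
    return base
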
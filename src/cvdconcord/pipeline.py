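"""End-to-end orchestration: cohort -> flags -> scores -> decisions -> reports.

Produces the three result surfaces of the analysis:

* an agreement matrix comparing each dichotomized 10-year score
  (Framingham >= 20%, SCORE >= 5%, ASCVD >= 7.5%) against the high 5-year
  D:A:D score (> 5%) on the agreement subset (non-diabetic, no prior CVD,
  TC <= 8, LDL <= 4.9 mmol/L);
* per-guideline statin-eligibility prevalences with Agresti-Coull
  intervals on the statin-naive subset, pairwise guideline kappas, and the
  relative increase of ACC/AHA over EACS eligibility;
* a risk-factor summary table: the whole cohort plus one column per
  high-risk stratum, counts (%) for categorical rows and median (Q1-Q3)
  for continuous rows (quantiles by linear interpolation).

Every report is recomputable from the exported per-patient CSV, and runs
are byte-identical for a fixed seed and config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import agreement as ag
from . import eligibility as el
from .cohort import (
    CohortOptions,
    PatientRecord,
    cohort_to_frame,
    flags_frame,
    load_cohort,
    select_agreement_subset,
    select_eligibility_subset,
    write_cohort,
)
from .riskengines import CoefficientSet, load_all_coefficients, score_patient
from .synthetic import CohortSpec, default_spec, generate_cohort

logger = logging.getLogger(__name__)

COMPARATORS = ("frs", "score", "ascvd")  # each compared against high DAD


class RunConfig(BaseModel):
    """Configuration for one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "csv"
    cohort_path: Optional[str] = None
    coeff_dir: Optional[str] = None
    seed: int = 0
    n: int = 254
    score_region: str = "high"
    out_dir: Optional[str] = None
    options: CohortOptions = Field(default_factory=CohortOptions)
    guidelines: tuple[str, ...] = el.GUIDELINES


def prepare_cohort(config: RunConfig) -> list[PatientRecord]:
    """Load the CSV cohort or generate the synthetic one."""
    if config.mode == "csv":
        if not config.cohort_path:
            raise ValueError("csv mode needs cohort_path")
        return load_cohort(config.cohort_path, config.options)
    if config.mode == "synthetic":
        return generate_cohort(default_spec(n=config.n, seed=config.seed))
    raise ValueError(f"unknown input mode {config.mode!r}")


def score_frame(
    cohort: Sequence[PatientRecord],
    coefficients: dict[str, CoefficientSet],
    score_region: str = "high",
) -> pd.DataFrame:
    """Per-patient risk fractions and dichotomized categories."""
    rows = []
    for p in cohort:
        r = score_patient(p, coefficients, score_region=score_region)
        rows.append(
            {
                "id": p.id,
                "frs10": r.frs10,
                "score10": r.score10,
                "dad5": r.dad5,
                "ascvd10": r.ascvd10,
                "frs_cat": r.frs_cat,
                "score_cat": r.score_cat,
                "frs_high": r.frs_cat == "high",
                "score_high": r.score_cat == "high",
                "dad_high": r.dad_high,
                "ascvd_elevated": r.ascvd_elevated,
            }
        )
    return pd.DataFrame(rows)


def run_agreement_analysis(
    cohort: Sequence[PatientRecord],
    coefficients: dict[str, CoefficientSet],
    score_region: str = "high",
) -> dict:
    """Agreement of each high score with the high DAD score, Table-3 shaped."""
    subset = select_agreement_subset(cohort)
    if not subset:
        raise ValueError("agreement subset is empty")
    logger.info("agreement subset: %d of %d records", len(subset), len(cohort))
    scores = score_frame(subset, coefficients, score_region)
    dad = scores["dad_high"].to_numpy()
    comparator_flags = {
        "frs": scores["frs_high"].to_numpy(),
        "score": scores["score_high"].to_numpy(),
        "ascvd": scores["ascvd_elevated"].to_numpy(),
    }
    report: dict = {"n": len(subset), "rows": {}}
    for name in COMPARATORS:
        table = ag.cross_tabulate(comparator_flags[name], dad)
        summary = ag.summarize_agreement(table)
        report["rows"][name] = _summary_to_dict(summary)
    return report


def _summary_to_dict(s: ag.AgreementSummary) -> dict:
    def est(e: ag.Estimate) -> dict:
        return {"value": e.value, "lower": e.lower, "upper": e.upper}

    return {
        "counts": {"a": s.table.a, "b": s.table.b, "c": s.table.c, "d": s.table.d},
        "observed": est(s.observed),
        "agreement_high": est(s.agreement_high),
        "agreement_low": est(s.agreement_low),
        "kappa": est(s.kappa),
        "kappa_band": s.kappa_band,
    }


def run_eligibility_analysis(
    cohort: Sequence[PatientRecord],
    coefficients: dict[str, CoefficientSet],
    score_region: str = "high",
    seed: int = 0,
    n_boot: int = 10_000,
) -> dict:
    """Statin-eligibility prevalences, pairwise kappas, and relative increase."""
    subset = select_eligibility_subset(cohort)
    if not subset:
        raise ValueError("eligibility subset is empty")
    logger.info("eligibility subset: %d of %d records (statin-naive)", len(subset), len(cohort))
    scores = score_frame(subset, coefficients, score_region)
    decisions = {
        "eacs": [el.eacs_decision(p, f) for p, f in zip(subset, scores["frs10"])],
        "esc_eas": [el.esc_eas_decision(p, s) for p, s in zip(subset, scores["score10"])],
        "acc_aha": [el.acc_aha_decision(p, a) for p, a in zip(subset, scores["ascvd10"])],
    }
    flags = {
        g: np.array([d.verdict == "recommended" for d in ds])
        for g, ds in decisions.items()
    }
    report: dict = {"n": len(subset), "guidelines": {}, "pairwise_kappa": {}}
    for g, ds in decisions.items():
        prop, (lo, hi), x, n = el.eligibility_prevalence(ds)
        report["guidelines"][g] = {
            "recommended": x, "n": n, "proportion": prop, "lower": lo, "upper": hi,
        }
    for g1, g2 in (("acc_aha", "eacs"), ("acc_aha", "esc_eas"), ("eacs", "esc_eas")):
        table = ag.cross_tabulate(flags[g1], flags[g2])
        try:
            est, band = ag.cohens_kappa(table)
            row = {"value": est.value, "lower": est.lower, "upper": est.upper, "band": band}
        except ag.DegenerateTableError:
            row = {"value": None, "lower": None, "upper": None, "band": None}
        report["pairwise_kappa"][f"{g1}_vs_{g2}"] = row
    rng = np.random.default_rng(seed)
    inc = ag.relative_increase(
        int(flags["acc_aha"].sum()),
        int(flags["eacs"].sum()),
        paired_flags=(flags["acc_aha"], flags["eacs"]),
        n_boot=n_boot,
        rng=rng,
    )
    report["relative_increase_acc_aha_vs_eacs"] = {
        "percent": inc.value, "lower": inc.lower, "upper": inc.upper,
    }
    return report


_CATEGORICAL_ROWS = [
    ("male", lambda p, f: p.sex == "male"),
    ("hypertension", lambda p, f: f.hypertension),
    ("diabetes", lambda p, f: p.diabetes),
    ("current_smoker", lambda p, f: p.smoking == "current"),
    ("ex_smoker", lambda p, f: p.smoking == "ex"),
    ("tc_gt_6_2", lambda p, f: p.total_chol is not None and p.total_chol > 6.2),
    ("tg_gt_2_26", lambda p, f: p.triglycerides is not None and p.triglycerides > 2.26),
    ("dyslipidemia", lambda p, f: f.dyslipidemia),
    ("family_history", lambda p, f: p.family_history_premature_cvd),
    ("metabolic_syndrome", lambda p, f: f.metabolic_syndrome),
    ("current_pi", lambda p, f: p.current_pi),
    ("current_abacavir", lambda p, f: p.current_abacavir),
    ("on_lipid_lowering", lambda p, f: p.on_lipid_lowering),
    ("on_bp_meds", lambda p, f: bool(p.on_bp_meds)),
]

_CONTINUOUS_ROWS = [
    ("age", lambda p: p.age),
    ("bmi", lambda p: p.bmi),
    ("art_duration", lambda p: p.art_duration),
]


def run_risk_factor_summary(
    cohort: Sequence[PatientRecord],
    coefficients: dict[str, CoefficientSet],
    score_region: str = "high",
    options: CohortOptions | None = None,
) -> pd.DataFrame:
    """Risk-factor prevalences overall and within each high-risk stratum."""
    from .cohort import derive_flags

    scores = score_frame(cohort, coefficients, score_region)
    strata = {
        "overall": np.ones(len(cohort), dtype=bool),
        "frs_ge_20": scores["frs_high"].to_numpy(),
        "score_ge_5": scores["score_high"].to_numpy(),
        "ascvd_ge_7.5": scores["ascvd_elevated"].to_numpy(),
        "dad_gt_5": scores["dad_high"].to_numpy(),
    }
    flags = [derive_flags(p, options) for p in cohort]
    out_rows = []
    for label, fn in _CATEGORICAL_ROWS:
        row: dict = {"row": label, "type": "count_pct"}
        for col, mask in strata.items():
            idx = np.flatnonzero(mask)
            count = sum(1 for i in idx if fn(cohort[i], flags[i]))
            pct = 100.0 * count / len(idx) if len(idx) else float("nan")
            row[col] = f"{count} ({pct:.1f})" if len(idx) else "0 (-)"
        out_rows.append(row)
    for label, fn in _CONTINUOUS_ROWS:
        row = {"row": label, "type": "median_iqr"}
        for col, mask in strata.items():
            idx = np.flatnonzero(mask)
            if len(idx) == 0:
                row[col] = "-"
                continue
            vals = np.array([fn(cohort[i]) for i in idx], dtype=float)
            q1, q2, q3 = np.percentile(vals, [25, 50, 75])  # type-7 interpolation
            row[col] = f"{q2:.1f} ({q1:.1f}-{q3:.1f})"
        out_rows.append(row)
    frame = pd.DataFrame(out_rows)
    frame.attrs["stratum_sizes"] = {k: int(v.sum()) for k, v in strata.items()}
    return frame


def run_all(config: RunConfig) -> dict:
    """Full pipeline; writes per-patient CSVs and report JSONs when out_dir set."""
    coefficients = load_all_coefficients(config.coeff_dir)
    cohort = prepare_cohort(config)
    agreement_report = run_agreement_analysis(cohort, coefficients, config.score_region)
    eligibility_report = run_eligibility_analysis(
        cohort, coefficients, config.score_region, seed=config.seed
    )
    summary = run_risk_factor_summary(cohort, coefficients, config.score_region, config.options)
    result = {
        "config": {
            "mode": config.mode,
            "seed": config.seed,
            "n": len(cohort),
            "score_region": config.score_region,
            "coefficient_checksums": {m: c.checksum for m, c in coefficients.items()},
        },
        "subset_sizes": {
            "total": len(cohort),
            "agreement": len(select_agreement_subset(cohort)),
            "eligibility": len(select_eligibility_subset(cohort)),
        },
        "agreement": agreement_report,
        "eligibility": eligibility_report,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out / "cohort.csv")
        flags_frame(cohort, config.options).to_csv(out / "cohort_flags.csv", index=False)
        score_frame(cohort, coefficients, config.score_region).to_csv(
            out / "scores.csv", index=False
        )
        summary.to_csv(out / "risk_factor_summary.csv", index=False)
        (out / "report.json").write_text(json.dumps(result, indent=2, sort_keys=True))
        logger.info("wrote reports to %s", out)
    result["risk_factor_summary"] = summary
    return result
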
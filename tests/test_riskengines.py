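"""Risk-engine spot checks, properties, and category boundaries.

The spot-check expectations were computed by evaluating each model's
linear predictor and survival form by hand (spreadsheet-style arithmetic)
from the same coefficient config files, independently of the engine code.
"""

import math

import pytest

from cvdconcord import (
    ascvd_elevated,
    dad_cvd_5y,
    dad_high,
    framingham_cvd_10y,
    frs_category,
    load_coefficients,
    pooled_cohort_ascvd_10y,
    score_category,
    score_fatal_cvd_10y,
    score_patient,
)
from cvdconcord.riskengines import CoefficientConfigError, ScoringError

from conftest import make_record

SPOT = make_record(
    id="spot", age=61, sex="male", smoking="current",
    total_chol=6.0, hdl=1.2, sbp=142, on_bp_meds=False,
)


class TestSpotChecks:
    """Frozen hand evaluations of each model from its config coefficients."""

    def test_framingham(self, coeffs):
        assert framingham_cvd_10y(SPOT, coeffs["frs_cvd"]) == pytest.approx(
            0.372504601545425, rel=1e-12
        )

    def test_framingham_published_example(self, coeffs):
        # 61-year-old woman, TC 180 mg/dL, HDL 47, SBP 124 untreated, smoker
        p = make_record(
            id="ex", age=61, sex="female", smoking="current",
            total_chol=180 / 38.67, hdl=47 / 38.67, sbp=124, on_bp_meds=False,
        )
        assert framingham_cvd_10y(p, coeffs["frs_cvd"]) == pytest.approx(0.1048, abs=5e-4)

    def test_score(self, coeffs):
        assert score_fatal_cvd_10y(SPOT, coeffs["score"]) == pytest.approx(
            0.13815901302732037, rel=1e-12
        )

    def test_dad(self, coeffs):
        p = make_record(
            id="dad", age=49, sex="male", smoking="current", sbp=125,
            total_chol=5.5, hdl=1.2, current_abacavir=True,
            years_lopinavir=2.0, art_duration=6.0,
        )
        assert dad_cvd_5y(p, coeffs["dad"]) == pytest.approx(
            0.055080682550307736, rel=1e-12
        )

    def test_pooled_cohort(self, coeffs):
        assert pooled_cohort_ascvd_10y(SPOT, coeffs["pce"]) == pytest.approx(
            0.20130260168822556, rel=1e-12
        )

    def test_pooled_cohort_reference_profiles(self, coeffs):
        # 55-year-old, TC 213 mg/dL, HDL 50, SBP 120 untreated, nonsmoker
        expected = {
            ("white", "male"): 0.054, ("white", "female"): 0.021,
            ("black", "male"): 0.061, ("black", "female"): 0.030,
        }
        for (race, sex), want in expected.items():
            p = make_record(
                id="ref", age=55, sex=sex, race=race, smoking="never",
                total_chol=213 / 38.67, hdl=50 / 38.67, sbp=120, on_bp_meds=False,
            )
            assert pooled_cohort_ascvd_10y(p, coeffs["pce"]) == pytest.approx(want, abs=1e-3)


class TestProperties:
    def test_all_scores_are_fractions(self, coeffs, cohort1k):
        for p in cohort1k:
            r = score_patient(p, coeffs)
            for v in (r.frs10, r.score10, r.dad5, r.ascvd10):
                assert 0.0 <= v <= 1.0

    def test_age_monotonicity(self, coeffs):
        """Older patients score higher, all else fixed.

        Asserted for Framingham, SCORE, DAD, and the male Pooled Cohort
        strata; the published female Pooled Cohort equation is genuinely
        non-monotone in age near 40 for smokers with adverse lipids, so it
        is not a valid invariant there.
        """
        young, old = make_record(age=45), make_record(age=65)
        assert framingham_cvd_10y(old, coeffs["frs_cvd"]) > framingham_cvd_10y(
            young, coeffs["frs_cvd"]
        )
        assert score_fatal_cvd_10y(old, coeffs["score"]) > score_fatal_cvd_10y(
            young, coeffs["score"]
        )
        assert dad_cvd_5y(old, coeffs["dad"]) > dad_cvd_5y(young, coeffs["dad"])
        assert pooled_cohort_ascvd_10y(old, coeffs["pce"]) > pooled_cohort_ascvd_10y(
            young, coeffs["pce"]
        )

    def test_sbp_monotonicity(self, coeffs):
        for sbp_lo, sbp_hi in [(90, 120), (120, 160), (160, 200)]:
            lo, hi = make_record(sbp=sbp_lo), make_record(sbp=sbp_hi)
            assert framingham_cvd_10y(hi, coeffs["frs_cvd"]) > framingham_cvd_10y(
                lo, coeffs["frs_cvd"]
            )
            assert score_fatal_cvd_10y(hi, coeffs["score"]) > score_fatal_cvd_10y(
                lo, coeffs["score"]
            )
            assert dad_cvd_5y(hi, coeffs["dad"]) > dad_cvd_5y(lo, coeffs["dad"])
            assert pooled_cohort_ascvd_10y(hi, coeffs["pce"]) > pooled_cohort_ascvd_10y(
                lo, coeffs["pce"]
            )

    def test_smoking_raises_every_score(self, coeffs):
        never, smoker = make_record(smoking="never"), make_record(smoking="current")
        assert framingham_cvd_10y(smoker, coeffs["frs_cvd"]) > framingham_cvd_10y(
            never, coeffs["frs_cvd"]
        )
        assert score_fatal_cvd_10y(smoker, coeffs["score"]) > score_fatal_cvd_10y(
            never, coeffs["score"]
        )
        assert dad_cvd_5y(smoker, coeffs["dad"]) > dad_cvd_5y(never, coeffs["dad"])
        assert pooled_cohort_ascvd_10y(smoker, coeffs["pce"]) > pooled_cohort_ascvd_10y(
            never, coeffs["pce"]
        )

    def test_score_combined_exceeds_each_cause(self, coeffs):
        """Summed fatal-cause risks dominate the CHD-only component."""
        c = coeffs["score"]
        p = SPOT
        w = (
            c.coefficients["chd"]["total_chol"] * (p.total_chol - 6.0)
            + c.coefficients["chd"]["sbp"] * (p.sbp - 120.0)
            + c.coefficients["chd"]["smoker"]
        )
        base = c.regions["high"]["male"]["chd"]
        s_a = math.exp(-math.exp(base["alpha"]) * (p.age - 20) ** base["p"])
        s_b = math.exp(-math.exp(base["alpha"]) * (p.age - 10) ** base["p"])
        chd_only = 1 - (s_b / s_a) ** math.exp(w)
        assert score_fatal_cvd_10y(p, c) >= chd_only

    def test_dominance_low_risk_below_high_risk(self, coeffs):
        low = make_record(
            age=40, sex="female", smoking="never", total_chol=4.0, hdl=1.8,
            ldl=2.0, sbp=105, dbp=65,
        )
        high = make_record(
            age=65, sex="male", smoking="current", total_chol=7.5, hdl=0.9,
            ldl=5.0, sbp=170, dbp=100,
        )
        assert score_fatal_cvd_10y(low, coeffs["score"]) < score_fatal_cvd_10y(
            high, coeffs["score"]
        )

    def test_abacavir_strictly_raises_dad_risk(self, coeffs, cohort1k):
        for p in cohort1k[:200]:
            on = p.model_copy(update={"current_abacavir": True})
            off = p.model_copy(update={"current_abacavir": False})
            assert dad_cvd_5y(on, coeffs["dad"]) > dad_cvd_5y(off, coeffs["dad"])

    def test_dad_reduces_to_conventional_core_without_art(self, coeffs):
        p = make_record(
            years_indinavir=0, years_lopinavir=0, current_abacavir=False,
            current_indinavir=False, current_lopinavir=False, art_duration=0,
        )
        c = coeffs["dad"].strata["all"]
        lp = (
            c["intercept"]
            + c["coefficients"]["age"] * p.age
            + c["coefficients"]["male"]
            + c["coefficients"]["total_chol"] * p.total_chol
            + c["coefficients"]["hdl"] * p.hdl
            + c["coefficients"]["sbp"] * p.sbp
        )
        assert dad_cvd_5y(p, coeffs["dad"]) == pytest.approx(
            1 - math.exp(-5 * math.exp(lp)), rel=1e-12
        )

    def test_treated_bp_scores_at_least_untreated(self, coeffs):
        untreated = make_record(sbp=140, on_bp_meds=False)
        treated = make_record(sbp=140, on_bp_meds=True)
        assert pooled_cohort_ascvd_10y(treated, coeffs["pce"]) >= pooled_cohort_ascvd_10y(
            untreated, coeffs["pce"]
        )
        assert framingham_cvd_10y(treated, coeffs["frs_cvd"]) >= framingham_cvd_10y(
            untreated, coeffs["frs_cvd"]
        )

    def test_unit_declaration_invariance(self, coeffs, cohort254, tmp_path):
        """mg/dL input converted at load scores identically to native mmol/L."""
        from cvdconcord import load_cohort, score_patient, write_cohort
        from cvdconcord.cohort import cohort_to_frame

        subset = cohort254[:25]
        native = tmp_path / "native.csv"
        write_cohort(subset, native)
        frame = cohort_to_frame(subset)
        for col in ("total_chol", "hdl", "ldl"):
            frame[col] *= 38.67
        frame["triglycerides"] *= 88.57
        frame["fasting_glucose"] *= 18.02
        mgdl = tmp_path / "mgdl.csv"
        frame.to_csv(mgdl, index=False)
        (tmp_path / "mgdl.csv.units.json").write_text('{"units": "mg/dL"}')
        for a, b in zip(load_cohort(native), load_cohort(mgdl)):
            ra, rb = score_patient(a, coeffs), score_patient(b, coeffs)
            assert rb.frs10 == pytest.approx(ra.frs10, rel=1e-10)
            assert rb.score10 == pytest.approx(ra.score10, rel=1e-10)
            assert rb.dad5 == pytest.approx(ra.dad5, rel=1e-10)
            assert rb.ascvd10 == pytest.approx(ra.ascvd10, rel=1e-10)


class TestCategories:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.0, "low"), (0.099, "low"), (0.10, "moderate"), (0.199, "moderate"),
         (0.20, "high"), (1.0, "high")],
    )
    def test_framingham_bands(self, value, expected):
        assert frs_category(value) == expected

    @pytest.mark.parametrize(
        "value, expected",
        [(0.009, "low"), (0.01, "moderate"), (0.049, "moderate"), (0.05, "high")],
    )
    def test_score_bands(self, value, expected):
        assert score_category(value) == expected

    def test_dad_cutoff_is_strict(self):
        assert not dad_high(0.05)
        assert dad_high(0.0500001)

    def test_ascvd_cutoff_is_inclusive(self):
        assert ascvd_elevated(0.075)
        assert not ascvd_elevated(0.0749)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            frs_category(1.2)


class TestErrorsAndConfig:
    def test_missing_predictor_names_field(self, coeffs):
        p = make_record(hdl=None)
        with pytest.raises(ScoringError, match="hdl"):
            framingham_cvd_10y(p, coeffs["frs_cvd"])

    def test_age_outside_framingham_range_warns(self, coeffs):
        p = make_record(age=78)
        with pytest.warns(UserWarning, match="30-74"):
            framingham_cvd_10y(p, coeffs["frs_cvd"])

    def test_pce_refuses_age_outside_40_79(self, coeffs):
        with pytest.raises(ScoringError, match="40-79"):
            pooled_cohort_ascvd_10y(make_record(age=39), coeffs["pce"])

    def test_race_other_scored_as_white(self, coeffs):
        other = make_record(race="other")
        white = make_record(race="white")
        assert pooled_cohort_ascvd_10y(other, coeffs["pce"]) == pooled_cohort_ascvd_10y(
            white, coeffs["pce"]
        )

    def test_config_checksum_and_validation(self, tmp_path):
        c = load_coefficients("frs_cvd")
        assert len(c.checksum) == 64
        bad = tmp_path / "frs_cvd.yaml"
        bad.write_text(
            "model_id: frs_cvd\nsource_citation: x\nstrata:\n"
            "  male: {coefficients: {ln_age: 1.0}, mean_lp: 0.0, baseline_survival: 1.5}\n"
            "  female: {coefficients: {ln_age: 1.0}, mean_lp: 0.0, baseline_survival: 0.9}\n"
        )
        with pytest.raises(CoefficientConfigError, match="baseline_survival"):
            load_coefficients("frs_cvd", bad)

    def test_unknown_model_rejected(self):
        with pytest.raises(CoefficientConfigError):
            load_coefficients("who_chart")
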
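import pytest

from cvdconcord import PatientRecord, default_spec, generate_cohort, load_all_coefficients


@pytest.fixture(scope="session")
def coeffs():
    return load_all_coefficients()


@pytest.fixture(scope="session")
def cohort254():
    """One default synthetic cohort at the study size."""
    return generate_cohort(default_spec(n=254, seed=11))


@pytest.fixture(scope="session")
def cohort1k():
    """A larger synthetic cohort for property tests over the generator support."""
    return generate_cohort(default_spec(n=1000, seed=7))


def make_record(**overrides) -> PatientRecord:
    """A fully-specified mid-risk record; override any field."""
    base = dict(
        id="T1",
        age=50,
        sex="male",
        smoking="never",
        sbp=120,
        dbp=75,
        on_bp_meds=False,
        total_chol=5.0,
        hdl=1.3,
        ldl=3.0,
        triglycerides=1.5,
        fasting_glucose=5.0,
        diabetes=False,
        prior_cvd_event=False,
        family_history_premature_cvd=False,
        bmi=24.0,
        art_duration=6.0,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record
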
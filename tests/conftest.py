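import pytest

from residualrisk import (
    AscvdSubtype,
    LLTRegimen,
    PatientRecord,
    ReachCoefficients,
    Sex,
    Smoking,
    StatinIntensity,
)
from residualrisk.reach import Baseline, Term, TermEncoding


def make_patient(**overrides) -> PatientRecord:
    """A valid baseline patient; tweak single fields per test."""
    base = dict(
        patient_id="P0001",
        ascvd_subtype=AscvdSubtype.CAD,
        ldl_c=93.0,
        age=68.0,
        sex=Sex.male,
        smoking=Smoking.non,
        diabetes=False,
        hypertension=True,
        chf=False,
        af=False,
        sbp=135.0,
        dbp=77.0,
        bmi=27.8,
        ckd_ge3=False,
        n_vascular_beds=1,
        event_within_1y=False,
        region="western_europe",
        llt=LLTRegimen(statin_intensity=StatinIntensity.high),
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def patient() -> PatientRecord:
    return make_patient()


@pytest.fixture
def flat_risk_coeffs() -> ReachCoefficients:
    """No covariate effects; every patient gets 10-year risk exactly 0.32."""
    return ReachCoefficients(
        name="flat-0.32",
        terms=(),
        baseline=Baseline(form="survival", s0=0.68 ** (1.0 / 6.0), reference_score=0.0),
    )


@pytest.fixture
def age_only_coeffs() -> ReachCoefficients:
    """Single hand-computable term: 0.01 per year of age, uncentered."""
    return ReachCoefficients(
        name="age-only",
        terms=(
            Term(
                name="age",
                coefficient=0.01,
                encoding=TermEncoding(kind="linear", field="age"),
            ),
        ),
        baseline=Baseline(form="survival", s0=0.95, reference_score=0.0),
    )
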
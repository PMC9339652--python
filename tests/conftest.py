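import numpy as np
import pytest

from npdecline.model import (
    Cohort,
    Diagnosis,
    Sex,
    Subject,
    TestBattery,
    TestId,
    Visit,
)
from npdecline.norms import published_norms


def make_battery(
    lm1=12.0, lm2=11.0, ta=35.0, tb=90.0, ani=20.0, veg=14.0
) -> TestBattery:
    return TestBattery(
        lm_immediate=lm1,
        lm_delayed=lm2,
        trails_a_seconds=ta,
        trails_b_seconds=tb,
        animals=ani,
        vegetables=veg,
    )


def make_subject(
    subject_id="S001",
    sex=Sex.FEMALE,
    education=16.0,
    age0=72.0,
    visit_specs=None,
) -> Subject:
    """Build a subject from (months, diagnosis, cdr, battery) tuples."""
    if visit_specs is None:
        visit_specs = [
            (0.0, Diagnosis.NORMAL, 0.0, make_battery()),
            (12.0, Diagnosis.NORMAL, 0.0, make_battery()),
            (24.0, Diagnosis.NORMAL, 0.0, make_battery()),
        ]
    visits = [
        Visit(
            subject_id=subject_id,
            visit_index=k,
            months_since_baseline=months,
            age_years=age0 + months / 12.0,
            diagnosis=diagnosis,
            cdr_global=cdr,
            scores=battery,
        )
        for k, (months, diagnosis, cdr, battery) in enumerate(visit_specs)
    ]
    return Subject(
        subject_id=subject_id, sex=sex, education_years=education, visits=visits
    )


@pytest.fixture(scope="session")
def norms():
    return published_norms()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_subject_cohort():
    a = make_subject("A01")
    b = make_subject(
        "B02",
        sex=Sex.MALE,
        visit_specs=[
            (0.0, Diagnosis.MCI, 0.5, make_battery(lm1=8.0)),
            (11.5, Diagnosis.MCI, 0.5, make_battery(lm1=7.0, lm2=None)),
        ],
    )
    return Cohort(subjects=[a, b], provenance="fixture")


def all_tests():
    return list(TestId)
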
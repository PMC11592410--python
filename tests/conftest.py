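import numpy as np
import pytest

from fibrotriage import PatientRecord, default_spec_from_reference_cohort, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def reference_spec():
    return default_spec_from_reference_cohort()


@pytest.fixture(scope="session")
def reference_cohort(reference_spec):
    """One seeded synthetic cohort with the published group structure (28 + 125)."""
    return generate(reference_spec, seed=11)


def make_record(
    id="s1",
    age=50.0,
    sex="male",
    ast=40.0,
    alt=25.0,
    platelets=200.0,
    albumin=4.0,
    bmi=30.0,
    ifg_or_diabetes=False,
    **kwargs,
):
    """A valid record with convenient defaults (fib4 = 2.0 at these values)."""
    return PatientRecord(
        id=id, age=age, sex=sex, ast=ast, alt=alt, platelets=platelets,
        albumin=albumin, bmi=bmi, ifg_or_diabetes=ifg_or_diabetes, **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record
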
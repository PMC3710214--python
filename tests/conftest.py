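import pytest

from mpsi_predict import load_reference_cohort, load_severe_mutations


@pytest.fixture(scope="session")
def cohort():
    return load_reference_cohort()


@pytest.fixture(scope="session")
def severe():
    return load_severe_mutations()


@pytest.fixture(scope="session")
def by_id(cohort):
    return {rec.id: rec for rec in cohort}
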
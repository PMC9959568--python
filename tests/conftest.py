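import pytest

from olfmap import derive_profiles, make_fixture_cohort
from olfmap.autocm import encode_variables, train_autocm


@pytest.fixture(scope="session")
def fixture_cohort():
    return make_fixture_cohort()


@pytest.fixture(scope="session")
def fixture_profiles(fixture_cohort):
    return derive_profiles(fixture_cohort.records)


@pytest.fixture(scope="session")
def fixture_dataset(fixture_profiles):
    return encode_variables(fixture_profiles)


@pytest.fixture(scope="session")
def fixture_model(fixture_dataset):
    return train_autocm(fixture_dataset)
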
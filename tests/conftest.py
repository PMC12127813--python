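import pytest

from crcgerm.fixtures import cohort_patients, plp_table
from crcgerm.simulate import SyntheticCohortSpec, gen_cohort
from crcgerm.tables import packaged_panel


@pytest.fixture(scope="session")
def panel():
    return packaged_panel()


@pytest.fixture(scope="session")
def plp_df():
    return plp_table()


@pytest.fixture(scope="session")
def patients100():
    return cohort_patients()


@pytest.fixture(scope="session")
def cohort_seed1():
    """A full synthetic cohort at the default study conditions, seed 1."""
    return gen_cohort(SyntheticCohortSpec(seed=1))
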
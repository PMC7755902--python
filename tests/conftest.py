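import numpy as np
import pytest

from cohortcompare.signatures import load_catalog
from cohortcompare.synthetic import CohortConfig, generate_cohorts


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete two-cohort bundle shared across tests."""
    return generate_cohorts(CohortConfig(n_samples_per_cohort=60, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
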
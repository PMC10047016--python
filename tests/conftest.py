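import numpy as np
import pytest

from cemradial import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A small, fast cohort configuration shared across tests."""
    return CohortConfig(n_findings=24, image_size=64, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
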
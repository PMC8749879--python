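import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fatiguekit as fk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cfg():
    return fk.CohortConfig(seed=11)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return fk.CohortConfig(seed=11).noiseless()


@pytest.fixture(scope="session")
def default_dataset(default_cfg):
    return fk.simulate_cohort(default_cfg)


@pytest.fixture(scope="session")
def noiseless_table(noiseless_cfg):
    return fk.simulate_parameter_table(noiseless_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
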
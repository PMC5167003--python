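import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import blockdecode as bd

# deterministic property testing: fixed database-free profile
settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paradigm():
    """The study's block schedule: five 30-s task/rest cycles, task first."""
    return bd.Paradigm(30.0, 5, 1)


@pytest.fixture(scope="session")
def small_grid():
    return bd.GridSpec(16, 16, 4)


@pytest.fixture(scope="session")
def small_params(small_grid):
    return bd.SynthParams(grid=small_grid)


@pytest.fixture(scope="session")
def small_subject(small_params, paradigm):
    return bd.generate_subject(small_params, 42, paradigm)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
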
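import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lipidcea import prepare_model, synthesize_inputs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle():
    """Full base-case synthetic bundle: 30 LDL-C subgroups per sex."""
    return synthesize_inputs(seed=1)


@pytest.fixture(scope="session")
def default_prepared(default_bundle):
    return prepare_model(default_bundle)


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced bundle for fast end-to-end runs (2 subgroups per sex)."""
    return synthesize_inputs({"n_per_sex": 2}, seed=3)


@pytest.fixture(scope="session")
def small_prepared(small_bundle):
    return prepare_model(small_bundle)


@pytest.fixture(scope="session")
def small_grid():
    return np.array([0.8, 1.6, 2.4, 3.2, 4.0])
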
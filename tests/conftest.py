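import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mscea

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Default realistic parameter set: the 14-drug portfolio with the
    printed strategy profiles and synthetic supplementary inputs."""
    return mscea.generate_parameter_set()


@pytest.fixture(scope="session")
def cau(params):
    return params.strategies["CAU"]


@pytest.fixture(scope="session")
def sdm(params):
    return params.strategies["SDM"]


@pytest.fixture(scope="session")
def small_params():
    """A compact synthetic portfolio for structural tests."""
    return mscea.generate_parameter_set(mscea.GeneratorConfig(seed=42, n_dmds=6))


@pytest.fixture()
def fresh_params():
    """A mutable copy for tests that edit parameters in place."""
    import copy
    return copy.deepcopy(mscea.generate_parameter_set())
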
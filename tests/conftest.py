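import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mingled import Model
from mingled.reference import reference_parameters, reference_state

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return Model()


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_state():
    return reference_state()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
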
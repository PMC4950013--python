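import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20160406)


@pytest.fixture
def random_profiles(rng):
    """Random correlation profiles comfortably inside the [-1, 1] box."""
    return rng.uniform(-0.6, 0.6, size=(20, 10))


@pytest.fixture(scope="session")
def survey_cohort():
    """A mid-sized circumplex survey (n = 500) shared across tests."""
    from valuewave.simulate import CircumplexSpec, gen_value_responses

    spec = CircumplexSpec(n_participants=500, seed=11)
    return spec, gen_value_responses(spec)
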
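import numpy as np
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
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_session():
    """A 120-s mixed run/rest synthetic session shared across test modules."""
    import lfpkit as lk

    params = lk.SimulationParams(duration_s=120.0, seed=5)
    return lk.simulate_session(params, seed=5)
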
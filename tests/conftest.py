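import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_cfg():
    """Short-trial arena config for tests that only need a few deliveries."""
    from kinforage import ArenaConfig
    return ArenaConfig(trial_duration=20.0)
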
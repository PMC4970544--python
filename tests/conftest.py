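import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_chain():
    from vwforce import ChainConfig
    return ChainConfig(n_beads=6)


@pytest.fixture(scope="session")
def study_events():
    """Rupture events at the nine study velocities from known kinetics."""
    from vwforce import STUDY_VELOCITIES, gen_rupture_dataset
    return gen_rupture_dataset(koff=0.01, x_beta=0.3,
                               velocities=STUDY_VELOCITIES,
                               keff_mean=10.0, keff_sd=2.0,
                               n_per_velocity=300, seed=42)
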
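import numpy as np
import pytest
from hypothesis import settings

from gridcode.simulate import SimSpec, simulate_session

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def noiseless_session():
    """Single-run noiseless session: every estimator should be near-exact."""
    spec = SimSpec(seed=11, n_runs=1, noise_sd=0.0, phi_jitter_sd=0.0, drift=0.0,
                   grid_shape=(6, 6, 2), roi_fraction=0.5,
                   n_events_per_run=120, run_length=360.0)
    return simulate_session(spec)


@pytest.fixture(scope="session")
def default_session():
    """Two-run session at the generator's default study conditions."""
    return simulate_session(SimSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
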
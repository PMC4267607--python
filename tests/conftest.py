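import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ethoseg import SimConfig, calibrate_thresholds, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table500():
    """ARL0=500 thresholds long enough for null run-length experiments."""
    return calibrate_thresholds(500, max_length=800, startup=20,
                                n_reps=3000, seed=5)


@pytest.fixture(scope="session")
def table50k():
    """ARL0=50000 thresholds covering a 200-record bout."""
    return calibrate_thresholds(50000, max_length=250, startup=20,
                                n_reps=2000, seed=8)


@pytest.fixture(scope="session")
def small_dataset():
    """20 annotated bouts from the shipped default config."""
    return simulate_dataset(SimConfig(), 20, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
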
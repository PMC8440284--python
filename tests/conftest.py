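import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petblock import CohortConfig, default_schedule
from petblock.synth import generate_input_function

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def truth_input():
    """A noiseless ground-truth input function from the generator."""
    cfg = CohortConfig(noise_scale=0.0)
    _, _, inp, _ = generate_input_function(cfg, seed=5)
    return inp


@pytest.fixture(scope="session")
def noiseless_config():
    return CohortConfig(noise_scale=0.0)


def small_regions(n=3):
    items = list(CohortConfig().regions.items())[:n]
    return dict(items)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
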
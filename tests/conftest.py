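import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dysmorph.synthetic import make_template, pinocchio_pair

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def template200():
    """Small symmetric face template with its bilateral map and regions."""
    return make_template(200, seed=0)


@pytest.fixture(scope="session")
def noisy_pinocchio():
    """500-landmark Pinocchio pair with realistic scan noise (sigma 0.2 mm)."""
    return pinocchio_pair(500, seed=5, noise_sigma=0.2)


@pytest.fixture(scope="session")
def clean_pinocchio():
    """Noiseless 400-landmark Pinocchio pair (exact-recovery scenarios)."""
    return pinocchio_pair(400, seed=1, noise_sigma=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
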
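import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gpqpi import scenes

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mono600():
    """Monochromatic 600 nm line."""
    return scenes.make_spectrum(600.0, 50.0, 1)


@pytest.fixture(scope="session")
def broadband():
    """The 600/50 nm Gaussian band sampled at 21 lines."""
    return scenes.make_spectrum(600.0, 50.0, 21)


@pytest.fixture(scope="session")
def flat_scene():
    """Blank mirror at zero displacement, 256^2 at 0.5 um pitch."""
    return scenes.mirror_scene((256, 256), 0.5, 0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
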
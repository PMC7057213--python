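import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from errsmear import Structure, make_target

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_target():
    """30-residue compact CA trace, fixed seed."""
    return make_target(30, seed=3)


@pytest.fixture(scope="session")
def medium_target():
    """100-residue compact CA trace, fixed seed."""
    return make_target(100, seed=1)


def random_structure(rng, n=None):
    """Arbitrary (non-physical) structure for I/O round-trip tests."""
    n = n or int(rng.integers(3, 30))
    coords = rng.uniform(-99, 99, size=(n, 3))
    b = rng.uniform(0, 99, size=n)
    return Structure.from_coords(coords, identifier="random", b_factors=b)
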
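import numpy as np
import pytest
from hypothesis import settings

from batquant import PhantomSpec, Volume3D, make_phantom, uniform_grid

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def grid8():
    return uniform_grid((8, 8, 8), spacing=(2.0, 2.0, 2.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-parameter phantom shared across read-only tests."""
    return make_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return make_phantom(PhantomSpec(seed=11, mr_snr=None, pet_noise_sd=0.0))


def make_volume(values, spacing=(1.0, 1.0, 1.0), units="arbitrary"):
    values = np.asarray(values, dtype=float)
    return Volume3D(values=values, grid=uniform_grid(values.shape, spacing),
                    units=units)


@pytest.fixture
def volume_factory():
    return make_volume
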
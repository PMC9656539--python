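import numpy as np
import pytest

from lobereg.phantom import PhantomSpec, make_atlas_phantom, make_phantom_pair


@pytest.fixture(scope="session")
def clean_atlas():
    """Noise-free 64^3 atlas phantom shared across tests."""
    return make_atlas_phantom(PhantomSpec(noise_sd=0))


@pytest.fixture(scope="session")
def clean_atlas_small():
    """Noise-free 32^3 atlas phantom for fast tests."""
    return make_atlas_phantom(PhantomSpec(shape=(32, 32, 32), noise_sd=0))


@pytest.fixture(scope="session")
def phantom_pair():
    """Noise-free atlas + subject deformed by a known 3-voxel field."""
    return make_phantom_pair(PhantomSpec(noise_sd=0), amplitude=3.0, scale=8.0, field_seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
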
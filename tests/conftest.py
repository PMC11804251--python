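import numpy as np
import pytest

from tomopick import ParticleSet, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_volume(rng):
    """A 24^3 volume of standard-normal noise."""
    return Volume(rng.normal(size=(24, 24, 24)).astype(np.float32), voxel_size=10.0)


@pytest.fixture
def small_particles():
    """Three well-separated particles (diameter 10 px at 10 A/px) in a 32^3 grid."""
    coords = np.array([[8.0, 8.0, 8.0], [22.0, 10.0, 12.0], [12.0, 22.0, 24.0]])
    return ParticleSet(coords, diameter=100.0, voxel_size=10.0)
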
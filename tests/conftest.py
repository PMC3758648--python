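import numpy as np
import pytest

from hypercal.datamodel import SpectralCube, SpectralLibrary, make_wavelength_axis
from hypercal.simulate import default_axis, default_scene, preset, render_scene


@pytest.fixture(scope="session")
def axis32():
    """The standard acquisition grid: 462-648 nm in 6 nm bands."""
    return default_axis()


@pytest.fixture(scope="session")
def axis5():
    return make_wavelength_axis(500, 540, 10)


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


@pytest.fixture(scope="session")
def confocal():
    return preset("confocal")


@pytest.fixture(scope="session")
def widefield():
    return preset("widefield")


@pytest.fixture(scope="session")
def confocal_library(confocal):
    """Peak-normalized three-endmember library on the standard axis."""
    return confocal.library()


@pytest.fixture
def small_scene(confocal_library):
    """A 32x32 rendered scene: (truth abundances, noise-free cube)."""
    return render_scene(default_scene((32, 32), seed=7), confocal_library)


def random_cube(rng, shape=(4, 4), axis=None, scale=100.0):
    axis = axis or make_wavelength_axis(462, 648, 6)
    data = rng.uniform(0, scale, size=(*shape, axis.n_bands))
    return SpectralCube(data, axis, 16)
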
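import numpy as np
import pytest

from megpeb.geometry import build_leadfield, generate_fixture_geometry


@pytest.fixture(scope="session")
def small_geometry():
    """A 300-vertex fixture shell with the standard dipole sites."""
    return generate_fixture_geometry(300, seed=7)


@pytest.fixture(scope="session")
def small_leadfield(small_geometry):
    mesh, sensors, sphere = small_geometry
    return build_leadfield(mesh, sensors, sphere)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
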
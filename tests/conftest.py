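import numpy as np
import pytest

from morphoqc import (
    LandmarkConfiguration,
    SyntheticSpec,
    make_template,
    simulate_hierarchy,
)


@pytest.fixture(scope="session")
def sphere_mesh():
    """Closed icosphere template at head-like scale (162 vertices)."""
    return make_template("sphere", 162)


@pytest.fixture(scope="session")
def sphere_mesh_642():
    return make_template("sphere", 642)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_configuration(rng, n=50, scale=40.0):
    return LandmarkConfiguration(rng.normal(0.0, scale, size=(n, 3)))


def random_rotation(rng):
    """Uniform proper rotation via QR decomposition of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    return q


@pytest.fixture(scope="session")
def small_study(sphere_mesh):
    """A small balanced two-camera hierarchy with known noise structure."""
    spec = SyntheticSpec(
        template=sphere_mesh,
        n_individuals=3,
        R=3,
        M=3,
        sigma_reg=0.05,
        sigma_tech=0.2,
        sigma_part=0.0,
        bias_amplitude=0.5,
        bias_field=np.ones(sphere_mesh.n_vertices),
        individual_shape_sd=1.0,
        seed=7,
    )
    cset, truth = simulate_hierarchy(spec)
    return cset, truth
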
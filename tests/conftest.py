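import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import femurdisp as fd

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coarse_spec():
    """Fast low-resolution phantom spec for unit tests."""
    return fd.PhantomSpec(mesh_resolution=3.0, vertex_noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def coarse_pair(coarse_spec):
    """Null-displacement phantom pair at coarse resolution."""
    return fd.generate_phantom_pair(coarse_spec)


@pytest.fixture()
def tetrahedron():
    """Smallest closed triangulated surface."""
    vertices = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return fd.TriangleMesh(vertices, faces)


@pytest.fixture(scope="session")
def sphere_points():
    """Deterministic points on the unit sphere surface (for scaling in tests)."""
    rng = np.random.default_rng(12345)
    p = rng.normal(size=(500, 3))
    return p / np.linalg.norm(p, axis=1, keepdims=True)
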
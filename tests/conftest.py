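import numpy as np
import pytest

from meshmorph.mesh import TriMesh
from meshmorph.synthetic import make_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def icosphere2():
    """Unit icosphere, 162 vertices / 320 faces."""
    return make_template("icosphere", 2)


@pytest.fixture
def tetrahedron():
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(verts, faces)


def random_rotation(rng):
    """Uniform-ish random rotation matrix with det +1."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
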
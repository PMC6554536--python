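import numpy as np
import pytest

from scleramap.forward import PressureProtocol
from scleramap.mesh import TriSurfaceMesh, generate_hemisphere_shell


@pytest.fixture(scope="session")
def hemisphere():
    """Small posterior-shell stand-in: R = 12 mm, apical hole, ~2.5 mm edges."""
    return generate_hemisphere_shell(12.0, 1.75, 2.5, seed=0)


@pytest.fixture(scope="session")
def fine_hemisphere():
    """Hemisphere at 1.25 mm edges (used by solver/inverse tests)."""
    return generate_hemisphere_shell(12.0, 1.75, 1.25, seed=0)


@pytest.fixture(scope="session")
def protocol():
    return PressureProtocol(5.0, (15.0, 30.0, 45.0))


@pytest.fixture
def strip_mesh():
    """Flat 2 x 8 strip of right triangles in the z = 0 plane.

    Elements come in left/right pairs per cell column; useful for building
    labeled fixtures by hand.
    """
    nx, ny = 8, 2
    xs, ys = np.meshgrid(np.arange(nx + 1, dtype=float), np.arange(ny + 1, dtype=float))
    nodes = np.column_stack([xs.ravel(), ys.ravel(), np.zeros((nx + 1) * (ny + 1))])
    tris = []
    for j in range(ny):
        for i in range(nx):
            a = j * (nx + 1) + i
            b = a + 1
            c = a + nx + 1
            d = c + 1
            tris.append([a, b, d])
            tris.append([a, d, c])
    return TriSurfaceMesh(nodes, np.array(tris, dtype=int))
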
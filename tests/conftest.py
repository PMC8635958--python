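import numpy as np
import pytest

from mechanotaxis import build_disk_mesh
from mechanotaxis.mesh import CellMesh, _canonical


@pytest.fixture(scope="session")
def disk_mesh():
    """Small disk mesh shared by read-only geometry tests."""
    return build_disk_mesh(diameter=10.0, n_membrane=24, n_interior=40, seed=7)


@pytest.fixture(scope="session")
def paper_mesh():
    """The full-size cell: 45 peripheral + 421 internal nodes, 10 μm."""
    return build_disk_mesh(diameter=10.0, n_membrane=45, n_interior=421, seed=3)


def make_polygon_mesh(poly):
    """A membrane-only CellMesh (no usable triangulation) for polygon tests."""
    poly = np.asarray(poly, dtype=float)
    tri = _canonical(np.array([[0, 1, 2]]))
    mesh = CellMesh(membrane=poly, interior=poly.mean(axis=0, keepdims=True),
                    triangles=tri, reference_angles=np.zeros((1, 3)))
    return mesh


@pytest.fixture
def square_mesh():
    """Unit square with one interior node connected to all four corners."""
    square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    interior = np.array([[0.3, 0.4]])
    tris = _canonical(np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]]))
    mesh = CellMesh(membrane=square, interior=interior, triangles=tris,
                    reference_angles=np.zeros((4, 3)))
    mesh.reference_angles = mesh.corner_angles.copy()
    return mesh
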
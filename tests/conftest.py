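import numpy as np
import pytest

from phytomesh.mesh import BOUNDARY, TissueMesh, generate_grid_tissue


def single_cell_mesh(points, n_chemicals=1, amounts=None):
    """One polygonal cell with one boundary wall per edge."""
    mesh = TissueMesh(n_chemicals)
    for x, y in points:
        mesh.add_node(x, y, at_boundary=True)
    cell = mesh.add_cell(range(len(points)))
    if amounts is not None:
        cell.chem_amounts[:] = amounts
    n = len(points)
    for i in range(n):
        mesh.add_wall(cell.id, BOUNDARY, [i, (i + 1) % n])
    return mesh


@pytest.fixture
def unit_square():
    return single_cell_mesh([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def grid5():
    return generate_grid_tissue(5, 5, 1.0, 1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
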
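import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from phytomesh.mesh import (
    BOUNDARY,
    Cell,
    DivisionError,
    GeometryError,
    TissueMesh,
    divide_cell,
    generate_grid_tissue,
    inertia_axis,
    partition_daughter_state,
    polygon_area,
    ring_is_simple,
    split_long_edges,
    validate_mesh,
)

from conftest import single_cell_mesh


class TestPolygonArea:
    @pytest.mark.parametrize("ring,expected", [
        ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
        ([(0, 0), (2, 0), (0, 2)], 2.0),
        ([(0, 0), (0, 1), (1, 1), (1, 0)], -1.0),  # clockwise
    ])
    def test_shoelace(self, ring, expected):
        assert polygon_area(ring) == pytest.approx(expected, abs=1e-15)

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            polygon_area([(0, 0), (1, 1)])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
                    min_size=3, max_size=8))
    def test_matches_shapely_magnitude(self, pts):
        ours = abs(polygon_area(pts))
        assert ours == pytest.approx(Polygon(pts).area, abs=1e-9)


class TestInertiaAxis:
    def test_rectangle(self):
        c, axis, iso = inertia_axis([(0, 0), (2, 0), (2, 1), (0, 1)])
        assert c == pytest.approx([1.0, 0.5])
        assert axis == pytest.approx([1.0, 0.0])
        assert not iso

    def test_square_is_isotropic_with_deterministic_axis(self):
        _, axis, iso = inertia_axis([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert iso
        assert axis == pytest.approx([1.0, 0.0])

    def test_rotated_rectangle(self):
        theta = math.radians(30)
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        pts = (np.array([(0, 0), (2, 0), (2, 1), (0, 1)]) - [1, 0.5]) @ rot.T
        _, axis, iso = inertia_axis(pts)
        assert not iso
        expected = rot @ np.array([1.0, 0.0])
        assert abs(abs(axis @ expected) - 1.0) < 1e-9

    def test_degenerate_polygon(self):
        with pytest.raises(GeometryError):
            inertia_axis([(0, 0), (1, 0), (2, 0)])


class TestSplitLongEdges:
    def test_below_threshold_noop(self, unit_square):
        assert split_long_edges(unit_square, 2.0) == 0

    def test_all_four_edges_split(self, unit_square):
        n = split_long_edges(unit_square, 0.8)
        assert n == 4
        cell = next(iter(unit_square.cells.values()))
        assert len(cell.node_ids) == 8
        assert unit_square.total_area() == pytest.approx(1.0, rel=1e-12)
        assert validate_mesh(unit_square) == []

    def test_shared_edge_node_in_both_rings(self):
        mesh = generate_grid_tissue(1, 2, 2.0, 1)  # edges of length 2
        before = {cid: len(c.node_ids) for cid, c in mesh.cells.items()}
        n = split_long_edges(mesh, 1.5)
        assert n == 7  # every edge of the two squares exceeds 1.5
        assert validate_mesh(mesh) == []
        # the shared internal edge's midpoint must appear in both rings
        shared = [w for w in mesh.walls.values() if not w.is_boundary][0]
        mid = shared.node_path[1]
        for cid in (shared.cell_a, shared.cell_b):
            assert mid in mesh.cells[cid].node_ids
            assert len(mesh.cells[cid].node_ids) == before[cid] + 4


class TestDivideCell:
    def test_rectangle_inertia_split(self):
        mesh = single_cell_mesh([(0, 0), (2, 0), (2, 1), (0, 1)])
        da, db = divide_cell(mesh, 0)
        assert mesh.cell_area(da) == pytest.approx(1.0, abs=2e-6)
        assert mesh.cell_area(db) == pytest.approx(1.0, abs=2e-6)
        assert validate_mesh(mesh) == []

    def test_area_conservation(self):
        mesh = single_cell_mesh([(0, 0), (2, 0), (2, 1), (0, 1)])
        da, db = divide_cell(mesh, 0)
        assert mesh.cell_area(da) + mesh.cell_area(db) == pytest.approx(2.0,
                                                                        abs=1e-9)

    def test_l_shape_against_offset_scan_oracle(self):
        pts = [(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)]
        mesh = single_cell_mesh(pts)
        _, axis, _ = inertia_axis(pts)
        # oracle: dense offset scan with shapely half-plane clipping
        poly = Polygon(pts)
        normal = axis
        proj = np.array(pts) @ normal
        best = None
        big = 100.0
        for t in np.linspace(proj.min(), proj.max(), 20001):
            # half-plane normal.p <= t as a big clipping rectangle
            d = np.array([-normal[1], normal[0]])
            p0 = normal * t
            quad = Polygon([p0 + d * big, p0 - d * big,
                            p0 - d * big - normal * big,
                            p0 + d * big - normal * big])
            a = poly.intersection(quad).area
            err = abs(a - poly.area / 2)
            if best is None or err < best[0]:
                best = (err, t)
        da, db = divide_cell(mesh, 0)
        a1, a2 = mesh.cell_area(da), mesh.cell_area(db)
        assert abs(a1 - a2) / (a1 + a2) <= 1e-6
        # the bisection must do at least as well as the dense scan's grid
        assert abs(a1 - poly.area / 2) <= best[0] + poly.area * 1e-6

    def test_neighbor_ring_gains_cut_node(self):
        mesh = generate_grid_tissue(1, 2, 1.0, 1)
        left = sorted(mesh.cells)[0]
        right = sorted(mesh.cells)[1]
        n_before = len(mesh.cells[right].node_ids)
        divide_cell(mesh, left, axis=(1.0, 0.0))  # horizontal cut line
        assert len(mesh.cells[right].node_ids) == n_before + 1
        assert validate_mesh(mesh) == []

    def test_dead_cell_rejected(self, unit_square):
        unit_square.cells[0].alive = False
        with pytest.raises(DivisionError):
            divide_cell(unit_square, 0)

    def test_random_polygons_contract(self):
        """Equal-area contract over randomized convex and star polygons."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(4, 9))
            if trial % 2 == 0:  # convex: hull of random points
                raw = rng.uniform(-1, 1, size=(n + 4, 2))
                hull = Polygon(raw).convex_hull.exterior.coords[:-1]
                pts = list(hull)
            else:  # simple star-shaped: jittered radii around a circle
                angles = np.sort(rng.uniform(0, 2 * math.pi, n))
                radii = rng.uniform(0.5, 1.5, n)
                pts = [(r * math.cos(a), r * math.sin(a))
                       for a, r in zip(angles, radii)]
            if polygon_area(pts) < 0:
                pts = pts[::-1]
            if not ring_is_simple(pts):
                continue
            mesh = single_cell_mesh(pts, amounts=[rng.uniform(1, 10)])
            parent_area = mesh.cell_area(0)
            parent_amount = float(mesh.cells[0].chem_amounts[0])
            da, db = divide_cell(mesh, 0)
            half = parent_area / 2
            assert abs(mesh.cell_area(da) - half) <= 1e-6 * parent_area
            assert abs(mesh.cell_area(db) - half) <= 1e-6 * parent_area
            total = (float(mesh.cells[da].chem_amounts[0])
                     + float(mesh.cells[db].chem_amounts[0]))
            assert total == parent_amount  # exact conservation
            assert validate_mesh(mesh) == []


class TestPartitionDaughterState:
    @pytest.mark.parametrize("amount,area_a,area_b,expected", [
        (10.0, 1.0, 1.0, (5.0, 5.0)),
        (9.0, 2.0, 1.0, (6.0, 3.0)),
    ])
    def test_proportional(self, amount, area_a, area_b, expected):
        parent = Cell(0, [], np.array([amount]), 3.0)
        a = Cell(1, [], np.zeros(1), 0.0)
        b = Cell(2, [], np.zeros(1), 0.0)
        partition_daughter_state(parent, a, b, area_a, area_b)
        assert float(a.chem_amounts[0]) == pytest.approx(expected[0])
        assert float(b.chem_amounts[0]) == pytest.approx(expected[1])
        assert a.target_area + b.target_area == parent.target_area

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0, 1e6), st.floats(1e-3, 1e3), st.floats(1e-3, 1e3))
    def test_exact_conservation(self, amount, area_a, area_b):
        parent = Cell(0, [], np.array([amount]), 1.0)
        a = Cell(1, [], np.zeros(1), 0.0)
        b = Cell(2, [], np.zeros(1), 0.0)
        partition_daughter_state(parent, a, b, area_a, area_b)
        assert float(a.chem_amounts[0]) + float(b.chem_amounts[0]) == amount


class TestValidateMesh:
    def test_constructive_validity(self):
        assert validate_mesh(generate_grid_tissue(5, 5, 1.0, 2)) == []

    def test_clockwise_cell_flagged(self, unit_square):
        unit_square.cells[0].node_ids.reverse()
        issues = validate_mesh(unit_square)
        assert any("cell 0" in v and "counter-clockwise" in v for v in issues)

    def test_wall_path_not_in_ring_flagged(self, unit_square):
        unit_square.walls[0].node_path = [0, 2]  # a diagonal, not a ring edge
        issues = validate_mesh(unit_square)
        assert any("wall 0" in v for v in issues)


class TestGenerateGridTissue:
    def test_two_by_two_counts(self):
        mesh = generate_grid_tissue(2, 2, 1.0, 1)
        assert len(mesh.cells) == 4
        assert len(mesh.nodes) == 9
        assert len(mesh.walls) == 12
        assert sum(1 for w in mesh.walls.values() if not w.is_boundary) == 4
        assert mesh.total_area() == pytest.approx(4.0)

    def test_single_cell(self):
        mesh = generate_grid_tissue(1, 1, 1.0, 1)
        assert len(mesh.cells) == 1
        assert len(mesh.nodes) == 4
        assert all(w.is_boundary for w in mesh.walls.values())

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            generate_grid_tissue(0, 3, 1.0, 1)

    def test_boundary_flags(self):
        mesh = generate_grid_tissue(3, 3, 1.0, 1)
        interior = [n for n in mesh.nodes.values() if not n.at_boundary]
        assert len(interior) == 4  # the 2x2 inner nodes of a 4x4 node grid


class TestMutationInvariants:
    def test_random_operation_sequences_keep_mesh_valid(self):
        """Area additivity + topological closure under random split/divide."""
        rng = np.random.default_rng(7)
        mesh = generate_grid_tissue(4, 4, 1.0, 1)
        for cell in mesh.cells.values():
            cell.chem_amounts[:] = rng.uniform(0, 2)
        area0 = mesh.total_area()
        mass0 = sum(float(c.chem_amounts[0]) for c in mesh.cells.values())
        for _ in range(25):
            if rng.random() < 0.4:
                split_long_edges(mesh, float(rng.uniform(0.4, 1.2)))
            else:
                cid = int(rng.choice(sorted(mesh.cells)))
                try:
                    divide_cell(mesh, cid)
                except DivisionError:
                    pass
            assert validate_mesh(mesh) == []
        assert mesh.total_area() == pytest.approx(area0, rel=1e-9)
        mass1 = sum(float(c.chem_amounts[0]) for c in mesh.cells.values())
        assert mass1 == pytest.approx(mass0, rel=1e-12)
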
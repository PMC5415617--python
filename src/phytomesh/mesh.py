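"""Tissue geometry and topology.

A tissue is a planar mesh of polygonal cells. Cells are ordered rings of
shared nodes (vertices); neighboring cells share a *wall* — the apoplast
segment between them — which spans one or more mesh edges and carries
per-side attributes (e.g. transporter levels). Boundary walls face the
exterior and have ``cell_b == BOUNDARY``.

Conventions: cell rings are stored counter-clockwise (positive signed
area); a wall's ``node_path`` follows the orientation of its ``cell_a``
ring. Chemical state is stored as per-cell *amounts*; concentrations are
derived as amount/area, so growth dilutes and division conserves mass
automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Sentinel cell id for the exterior side of a boundary wall.
BOUNDARY = -1


class GeometryError(ValueError):
    """Invalid or degenerate geometry (too few points, zero area, ...)."""


class DivisionError(RuntimeError):
    """Cell division failed; the mesh was left unchanged."""


# ---------------------------------------------------------------------------
# polygon primitives


def polygon_area(points) -> float:
    """Signed shoelace area of a polygon ring (positive for CCW)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise GeometryError("polygon needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(points) -> np.ndarray:
    """Area centroid of a simple polygon."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if a == 0.0:
        raise GeometryError("zero-area polygon has no centroid")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return np.array([cx, cy])


def _second_moments(points):
    """Second area moments about the centroid: (Ixx, Iyy, Ixy)."""
    pts = np.asarray(points, dtype=float) - polygon_centroid(points)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    ixx = float(np.sum(cross * (y * y + y * yn + yn * yn))) / 12.0
    iyy = float(np.sum(cross * (x * x + x * xn + xn * xn))) / 12.0
    ixy = float(np.sum(cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y))) / 24.0
    return ixx, iyy, ixy


def inertia_axis(points, isotropy_tol: float = 1e-12):
    """Centroid and long axis (principal axis of the second area moments).

    Returns ``(centroid, axis, isotropic)``. ``axis`` is a unit vector with
    its first nonzero component positive. For an isotropic polygon (equal
    principal moments, e.g. a square) the +x axis is returned and
    ``isotropic`` is True.
    """
    area = polygon_area(points)
    if area <= 0:
        raise GeometryError("inertia axis requires a CCW polygon of positive area")
    c = polygon_centroid(points)
    ixx, iyy, ixy = _second_moments(points)
    # Covariance-like tensor of the area distribution; the long axis is the
    # eigenvector of the larger eigenvalue of [[Iyy, Ixy], [Ixy, Ixx]].
    tensor = np.array([[iyy, ixy], [ixy, ixx]])
    evals, evecs = np.linalg.eigh(tensor)
    spread = abs(evals[1] - evals[0])
    scale = max(abs(evals[0]), abs(evals[1]), 1.0)
    if spread <= isotropy_tol * scale:
        return c, np.array([1.0, 0.0]), True
    axis = evecs[:, int(np.argmax(evals))]
    # deterministic sign: first nonzero component positive
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return c, axis / np.linalg.norm(axis), False


def _orient(p, q, r) -> float:
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def _segments_cross(p1, p2, p3, p4) -> bool:
    """Proper or improper intersection of segments p1p2 and p3p4."""
    d1 = _orient(p3, p4, p1)
    d2 = _orient(p3, p4, p2)
    d3 = _orient(p1, p2, p3)
    d4 = _orient(p1, p2, p4)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return True

    def on_seg(a, b, c):
        return (
            min(a[0], b[0]) <= c[0] <= max(a[0], b[0])
            and min(a[1], b[1]) <= c[1] <= max(a[1], b[1])
        )

    if d1 == 0 and on_seg(p3, p4, p1):
        return True
    if d2 == 0 and on_seg(p3, p4, p2):
        return True
    if d3 == 0 and on_seg(p1, p2, p3):
        return True
    if d4 == 0 and on_seg(p1, p2, p4):
        return True
    return False


def ring_is_simple(points) -> bool:
    """True if the closed ring has no self-intersections and no repeats."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 3:
        return False
    if len({(float(p[0]), float(p[1])) for p in pts}) != n:
        return False
    for i in range(n):
        a1, a2 = pts[i], pts[(i + 1) % n]
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue  # adjacent edges share an endpoint
            b1, b2 = pts[j], pts[(j + 1) % n]
            if _segments_cross(a1, a2, b1, b2):
                return False
    return True


def clip_halfplane(points, normal, offset):
    """Clip polygon to the half-plane ``normal . p <= offset`` (Sutherland-Hodgman)."""
    pts = [np.asarray(p, dtype=float) for p in points]
    out = []
    n = len(pts)
    for i in range(n):
        cur, nxt = pts[i], pts[(i + 1) % n]
        d_cur = float(np.dot(normal, cur)) - offset
        d_nxt = float(np.dot(normal, nxt)) - offset
        if d_cur <= 0:
            out.append(cur)
        if (d_cur < 0 < d_nxt) or (d_nxt < 0 < d_cur):
            t = d_cur / (d_cur - d_nxt)
            out.append(cur + t * (nxt - cur))
    return np.array(out) if out else np.empty((0, 2))


# ---------------------------------------------------------------------------
# mesh data model


@dataclass
class Node:
    id: int
    x: float
    y: float
    fixed: bool = False
    at_boundary: bool = False

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Cell:
    id: int
    node_ids: list[int]
    chem_amounts: np.ndarray
    target_area: float
    cell_type: int = 0
    alive: bool = True
    base_area: float = 0.0  # birth area; division triggers reference it
    flags: dict = field(default_factory=dict)  # model-component scratch state


@dataclass
class Wall:
    id: int
    cell_a: int
    cell_b: int  # BOUNDARY for exterior walls
    node_path: list[int]  # oriented as in cell_a's ring
    rest_length: float
    stiffness: float = 1.0
    transporters_a: np.ndarray = field(default_factory=lambda: np.zeros(0))
    transporters_b: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def is_boundary(self) -> bool:
        return self.cell_b == BOUNDARY


class TissueMesh:
    """Nodes, polygonal cells, and walls of one tissue."""

    def __init__(self, n_chemicals: int = 0):
        self.nodes: dict[int, Node] = {}
        self.cells: dict[int, Cell] = {}
        self.walls: dict[int, Wall] = {}
        self.n_chemicals = int(n_chemicals)
        self._next_node_id = 0
        self._next_cell_id = 0
        self._next_wall_id = 0

    # -- construction helpers ------------------------------------------------

    def add_node(self, x, y, fixed=False, at_boundary=False, node_id=None) -> Node:
        nid = self._next_node_id if node_id is None else int(node_id)
        node = Node(nid, float(x), float(y), bool(fixed), bool(at_boundary))
        self.nodes[nid] = node
        self._next_node_id = max(self._next_node_id, nid + 1)
        return node

    def add_cell(self, node_ids, target_area=None, cell_type=0, chem_amounts=None,
                 cell_id=None, base_area=None) -> Cell:
        cid = self._next_cell_id if cell_id is None else int(cell_id)
        amounts = (np.zeros(self.n_chemicals) if chem_amounts is None
                   else np.asarray(chem_amounts, dtype=float).copy())
        cell = Cell(cid, list(node_ids), amounts, 0.0, int(cell_type))
        self.cells[cid] = cell
        area = self.cell_area(cid)
        cell.target_area = float(area if target_area is None else target_area)
        cell.base_area = float(area if base_area is None else base_area)
        self._next_cell_id = max(self._next_cell_id, cid + 1)
        return cell

    def add_wall(self, cell_a, cell_b, node_path, rest_length=None, stiffness=1.0,
                 transporters_a=None, transporters_b=None, wall_id=None) -> Wall:
        wid = self._next_wall_id if wall_id is None else int(wall_id)
        wall = Wall(wid, int(cell_a), int(cell_b), list(node_path), 1.0, float(stiffness))
        self.walls[wid] = wall
        wall.rest_length = float(self.wall_length(wid) if rest_length is None
                                 else rest_length)
        nt = self.n_chemicals
        wall.transporters_a = (np.zeros(nt) if transporters_a is None
                               else np.asarray(transporters_a, dtype=float).copy())
        wall.transporters_b = (np.zeros(nt) if transporters_b is None
                               else np.asarray(transporters_b, dtype=float).copy())
        self._next_wall_id = max(self._next_wall_id, wid + 1)
        return wall

    # -- geometry queries ----------------------------------------------------

    def node_pos(self, node_id: int) -> np.ndarray:
        n = self.nodes[node_id]
        return np.array([n.x, n.y])

    def cell_polygon(self, cell_id: int) -> np.ndarray:
        return np.array([[self.nodes[i].x, self.nodes[i].y]
                         for i in self.cells[cell_id].node_ids])

    def cell_area(self, cell_id: int) -> float:
        return polygon_area(self.cell_polygon(cell_id))

    def total_area(self) -> float:
        return sum(self.cell_area(c) for c in self.cells)

    def concentration(self, cell_id: int, chemical: int) -> float:
        cell = self.cells[cell_id]
        return float(cell.chem_amounts[chemical]) / self.cell_area(cell_id)

    def wall_length(self, wall_id: int) -> float:
        path = self.walls[wall_id].node_path
        return float(sum(
            math.dist((self.nodes[a].x, self.nodes[a].y),
                      (self.nodes[b].x, self.nodes[b].y))
            for a, b in zip(path[:-1], path[1:])))

    def cell_edges(self, cell_id: int):
        """Directed edges (node pairs) of a cell ring."""
        ring = self.cells[cell_id].node_ids
        return [(ring[i], ring[(i + 1) % len(ring)]) for i in range(len(ring))]

    def unique_edges(self) -> set[tuple[int, int]]:
        """Undirected edge set over all cell rings (each edge once)."""
        edges = set()
        for cid in self.cells:
            for a, b in self.cell_edges(cid):
                edges.add((a, b) if a < b else (b, a))
        return edges

    def edge_length(self, a: int, b: int) -> float:
        return math.dist((self.nodes[a].x, self.nodes[a].y),
                         (self.nodes[b].x, self.nodes[b].y))

    def walls_of_cell(self, cell_id: int) -> list[int]:
        return [w.id for w in self.walls.values()
                if w.cell_a == cell_id or w.cell_b == cell_id]

    def edge_wall_index(self) -> dict[tuple[int, int], int]:
        """Map undirected edge -> owning wall id."""
        index = {}
        for w in self.walls.values():
            for a, b in zip(w.node_path[:-1], w.node_path[1:]):
                index[(a, b) if a < b else (b, a)] = w.id
        return index

    def copy(self) -> "TissueMesh":
        other = TissueMesh(self.n_chemicals)
        for n in self.nodes.values():
            other.nodes[n.id] = Node(n.id, n.x, n.y, n.fixed, n.at_boundary)
        for c in self.cells.values():
            other.cells[c.id] = Cell(c.id, list(c.node_ids), c.chem_amounts.copy(),
                                     c.target_area, c.cell_type, c.alive,
                                     c.base_area, dict(c.flags))
        for w in self.walls.values():
            other.walls[w.id] = Wall(w.id, w.cell_a, w.cell_b, list(w.node_path),
                                     w.rest_length, w.stiffness,
                                     w.transporters_a.copy(), w.transporters_b.copy())
        other._next_node_id = self._next_node_id
        other._next_cell_id = self._next_cell_id
        other._next_wall_id = self._next_wall_id
        return other


# ---------------------------------------------------------------------------
# mesh operations


def _insert_in_ring(ring: list[int], a: int, b: int, new: int):
    """Insert ``new`` between adjacent ring members a and b (either order)."""
    n = len(ring)
    for i in range(n):
        u, v = ring[i], ring[(i + 1) % n]
        if (u, v) == (a, b) or (u, v) == (b, a):
            ring.insert(i + 1, new)
            return
    raise GeometryError(f"nodes {a},{b} not adjacent in ring")


def _insert_in_path(path: list[int], a: int, b: int, new: int):
    for i in range(len(path) - 1):
        u, v = path[i], path[i + 1]
        if (u, v) == (a, b) or (u, v) == (b, a):
            path.insert(i + 1, new)
            return
    raise GeometryError(f"nodes {a},{b} not adjacent in wall path")


def split_long_edges(mesh: TissueMesh, target_node_distance: float) -> int:
    """Bisect every edge longer than ``target_node_distance``.

    The midpoint node joins both adjacent cell rings and the owning wall's
    node path. Returns the number of insertions.
    """
    long_edges = [e for e in mesh.unique_edges()
                  if mesh.edge_length(*e) > target_node_distance]
    if not long_edges:
        return 0
    ewi = mesh.edge_wall_index()
    count = 0
    for a, b in sorted(long_edges):
        pa, pb = mesh.node_pos(a), mesh.node_pos(b)
        mid = 0.5 * (pa + pb)
        wall = mesh.walls[ewi[(a, b) if a < b else (b, a)]]
        node = mesh.add_node(mid[0], mid[1],
                             fixed=mesh.nodes[a].fixed and mesh.nodes[b].fixed,
                             at_boundary=wall.is_boundary)
        for cid in (wall.cell_a, wall.cell_b):
            if cid != BOUNDARY:
                _insert_in_ring(mesh.cells[cid].node_ids, a, b, node.id)
        _insert_in_path(wall.node_path, a, b, node.id)
        count += 1
    return count


def partition_daughter_state(parent: Cell, daughter_a: Cell, daughter_b: Cell,
                             area_a: float, area_b: float):
    """Split parent chemicals and target area between daughters.

    Amounts go proportional to daughter areas; the second daughter takes the
    exact remainder so every chemical is conserved to the last ulp.
    """
    frac = area_a / (area_a + area_b)
    daughter_a.chem_amounts = parent.chem_amounts * frac
    daughter_b.chem_amounts = parent.chem_amounts - daughter_a.chem_amounts
    daughter_a.target_area = parent.target_area * frac
    daughter_b.target_area = parent.target_area - daughter_a.target_area
    daughter_a.cell_type = daughter_b.cell_type = parent.cell_type
    daughter_a.flags = dict(parent.flags)
    daughter_b.flags = dict(parent.flags)


def _division_cut(mesh: TissueMesh, cell_id: int, normal: np.ndarray,
                  rel_tol: float = 1e-6, max_iter: int = 60):
    """Find the equal-area cut line ``normal . p = offset`` for a cell.

    Returns (offset, [(edge_index, point), (edge_index, point)]). Uses 1D
    bisection of the area residual along the normal direction.
    """
    pts = mesh.cell_polygon(cell_id)
    area = polygon_area(pts)
    proj = pts @ normal
    lo, hi = float(proj.min()), float(proj.max())
    half = 0.5 * area

    def area_below(t):
        clipped = clip_halfplane(pts, normal, t)
        return polygon_area(clipped) if clipped.shape[0] >= 3 else 0.0

    t0, t1 = lo, hi
    for _ in range(max_iter):
        tm = 0.5 * (t0 + t1)
        if area_below(tm) < half:
            t0 = tm
        else:
            t1 = tm
        if t1 - t0 <= 1e-15 * max(hi - lo, 1.0):
            break
    t = 0.5 * (t0 + t1)

    ring = mesh.cells[cell_id].node_ids
    n = len(ring)
    s = proj - t
    # nudge the line off any vertex it passes through exactly
    span = hi - lo
    guard = 1e-12 * max(span, 1.0)
    if np.any(np.abs(s) < guard):
        t += 8 * guard
        s = proj - t
    cuts = []
    for i in range(n):
        si, sj = s[i], s[(i + 1) % n]
        if (si < 0 < sj) or (sj < 0 < si):
            frac = si / (si - sj)
            point = pts[i] + frac * (pts[(i + 1) % n] - pts[i])
            cuts.append((i, point))
    return t, cuts


def divide_cell(mesh: TissueMesh, cell_id: int, axis=None,
                rel_tol: float = 1e-6) -> tuple[int, int]:
    """Divide a cell into two equal-area daughters.

    The division line runs perpendicular to the cell's axis of inertia
    (default), or along the supplied ``axis`` vector. The exact line offset
    is found by bisection so both daughter areas are within ``rel_tol``
    (relative to the parent) of half the parent area. Neighboring cells and
    wall bookkeeping are updated; a new wall joins the daughters.

    Returns ``(daughter_a_id, daughter_b_id)``. On failure raises
    :class:`DivisionError` and leaves the mesh unchanged.
    """
    cell = mesh.cells[cell_id]
    if not cell.alive:
        raise DivisionError(f"cell {cell_id} is not alive")
    pts = mesh.cell_polygon(cell_id)
    if not ring_is_simple(pts) or polygon_area(pts) <= 0:
        raise GeometryError(f"cell {cell_id} polygon is degenerate")

    if axis is None:
        _, long_axis, _ = inertia_axis(pts)
        # cut perpendicular to the long axis: offsets vary along the long axis
        normal = long_axis
    else:
        d = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise GeometryError("division axis must be nonzero")
        d = d / norm
        normal = np.array([-d[1], d[0]])  # offsets vary perpendicular to the line

    _, cuts = _division_cut(mesh, cell_id, normal, rel_tol=rel_tol)
    if len(cuts) != 2:
        raise DivisionError(
            f"division line crosses {len(cuts)} edges of cell {cell_id}, need 2")

    backup = mesh.copy()
    try:
        return _apply_division(mesh, cell_id, cuts, rel_tol)
    except Exception:
        mesh.nodes, mesh.cells, mesh.walls = backup.nodes, backup.cells, backup.walls
        mesh._next_node_id = backup._next_node_id
        mesh._next_cell_id = backup._next_cell_id
        mesh._next_wall_id = backup._next_wall_id
        raise


def _apply_division(mesh: TissueMesh, cell_id: int, cuts, rel_tol):
    cell = mesh.cells[cell_id]
    ring = list(cell.node_ids)
    n = len(ring)
    ewi = mesh.edge_wall_index()

    # create the two cut nodes and thread them into neighbor rings/wall paths
    new_ids = []
    for edge_idx, point in cuts:
        a, b = ring[edge_idx], ring[(edge_idx + 1) % n]
        wall = mesh.walls[ewi[(a, b) if a < b else (b, a)]]
        node = mesh.add_node(point[0], point[1], at_boundary=wall.is_boundary)
        _insert_in_path(wall.node_path, a, b, node.id)
        neighbor = wall.cell_b if wall.cell_a == cell_id else wall.cell_a
        if neighbor != BOUNDARY:
            _insert_in_ring(mesh.cells[neighbor].node_ids, a, b, node.id)
        new_ids.append(node.id)

    # parent ring with cut nodes inserted (later edge first keeps indices valid)
    (i1, _), (i2, _) = cuts
    n1, n2 = new_ids
    ring2 = list(ring)
    for idx, nid in sorted(zip((i1, i2), (n1, n2)), reverse=True):
        ring2.insert(idx + 1, nid)

    p1, p2 = ring2.index(n1), ring2.index(n2)
    if p1 > p2:
        p1, p2, n1, n2 = p2, p1, n2, n1
    ring_a = ring2[p1:p2 + 1]                 # n1 .. n2, closed by edge n2->n1
    ring_b = ring2[p2:] + ring2[:p1 + 1]      # n2 .. n1, closed by edge n1->n2

    area_a = polygon_area([[mesh.nodes[i].x, mesh.nodes[i].y] for i in ring_a])
    area_b = polygon_area([[mesh.nodes[i].x, mesh.nodes[i].y] for i in ring_b])
    if area_a <= 0 or area_b <= 0:
        raise DivisionError(f"division of cell {cell_id} produced a non-CCW daughter")

    da = mesh.add_cell(ring_a, target_area=0.0, cell_type=cell.cell_type)
    db = mesh.add_cell(ring_b, target_area=0.0, cell_type=cell.cell_type)
    da.base_area, db.base_area = area_a, area_b
    partition_daughter_state(cell, da, db, area_a, area_b)

    edges_a = {(min(a, b), max(a, b)) for a, b in
               zip(ring_a, ring_a[1:] + ring_a[:1])}

    # reassign / split every wall that touched the parent
    parent_walls = [w for w in mesh.walls.values()
                    if w.cell_a == cell_id or w.cell_b == cell_id]
    mean_stiffness = (sum(w.stiffness for w in parent_walls) / len(parent_walls)
                      if parent_walls else 1.0)
    for wall in parent_walls:
        orig_a, orig_b = wall.cell_a, wall.cell_b
        pieces = []
        for pos in range(1, len(wall.node_path) - 1):
            if wall.node_path[pos] in (n1, n2):
                pieces.append(pos)
        paths = []
        start = 0
        for pos in pieces:
            # only split if the two sides really belong to different daughters
            left = wall.node_path[start:pos + 1]
            rest = wall.node_path[pos:]
            owner_left = _path_owner(left, edges_a, da.id, db.id)
            owner_rest = _path_owner(rest, edges_a, da.id, db.id)
            if owner_left != owner_rest:
                paths.append(left)
                start = pos
        paths.append(wall.node_path[start:])
        total_actual = sum(_path_length(mesh, p) for p in paths)
        orig_rest = wall.rest_length
        for k, path in enumerate(paths):
            owner = _path_owner(path, edges_a, da.id, db.id)
            frac = _path_length(mesh, path) / total_actual if total_actual > 0 else 1.0
            if k == 0:
                target = wall
                target.node_path = path
                target.rest_length = orig_rest * frac
            else:
                target = mesh.add_wall(orig_a, orig_b, path,
                                       rest_length=orig_rest * frac,
                                       stiffness=wall.stiffness,
                                       transporters_a=wall.transporters_a,
                                       transporters_b=wall.transporters_b)
            if orig_a == cell_id:
                target.cell_a = owner
            else:
                target.cell_b = owner
            _orient_wall_path(mesh, target)

    # the new wall between the daughters, along the cut: edge n2->n1 in ring_a
    mesh.add_wall(da.id, db.id, [n2, n1], stiffness=mean_stiffness)

    del mesh.cells[cell_id]
    return da.id, db.id


def _path_length(mesh: TissueMesh, path: list[int]) -> float:
    return sum(mesh.edge_length(a, b) for a, b in zip(path[:-1], path[1:]))


def _path_owner(path: list[int], edges_a: set, id_a: int, id_b: int) -> int:
    key = (min(path[0], path[1]), max(path[0], path[1]))
    return id_a if key in edges_a else id_b


def _orient_wall_path(mesh: TissueMesh, wall: Wall):
    """Make node_path follow cell_a's ring orientation."""
    if wall.cell_a == BOUNDARY:
        wall.cell_a, wall.cell_b = wall.cell_b, wall.cell_a
        wall.transporters_a, wall.transporters_b = (wall.transporters_b,
                                                    wall.transporters_a)
    ring = mesh.cells[wall.cell_a].node_ids
    n = len(ring)
    a, b = wall.node_path[0], wall.node_path[1]
    for i in range(n):
        if ring[i] == a and ring[(i + 1) % n] == b:
            return
        if ring[i] == b and ring[(i + 1) % n] == a:
            wall.node_path.reverse()
            return
    # leave as-is; validate_mesh will flag genuine inconsistencies


# ---------------------------------------------------------------------------
# validation and fixtures


def _path_in_ring(path: list[int], ring: list[int]) -> bool:
    """Is ``path`` a contiguous (cyclic) sub-path of ``ring``?"""
    n = len(ring)
    if len(path) < 2:
        return False
    for start in range(n):
        if ring[start] == path[0]:
            if all(ring[(start + k) % n] == path[k] for k in range(len(path))):
                return True
    return False


def validate_mesh(mesh: TissueMesh) -> list[str]:
    """Check all mesh invariants; returns a list of violation messages."""
    issues = []
    for node in mesh.nodes.values():
        if not (math.isfinite(node.x) and math.isfinite(node.y)):
            issues.append(f"node {node.id}: non-finite position")
    for cell in mesh.cells.values():
        ring = cell.node_ids
        if len(ring) < 3 or len(set(ring)) != len(ring):
            issues.append(f"cell {cell.id}: ring must have >=3 distinct nodes")
            continue
        missing = [i for i in ring if i not in mesh.nodes]
        if missing:
            issues.append(f"cell {cell.id}: unknown nodes {missing}")
            continue
        pts = mesh.cell_polygon(cell.id)
        if not ring_is_simple(pts):
            issues.append(f"cell {cell.id}: polygon is self-intersecting")
        elif polygon_area(pts) <= 0:
            issues.append(f"cell {cell.id}: ring is not counter-clockwise")
        if np.any(cell.chem_amounts < 0):
            issues.append(f"cell {cell.id}: negative chemical amount")
        if len(cell.chem_amounts) != mesh.n_chemicals:
            issues.append(f"cell {cell.id}: chemical vector length mismatch")

    # edge sharing: every undirected edge in exactly 1 (boundary) or 2 rings
    edge_cells: dict[tuple[int, int], list[int]] = {}
    for cid in mesh.cells:
        for a, b in mesh.cell_edges(cid):
            edge_cells.setdefault((a, b) if a < b else (b, a), []).append(cid)
    for edge, owners in edge_cells.items():
        if len(owners) > 2:
            issues.append(f"edge {edge}: shared by {len(owners)} cells")

    # wall coverage: every edge covered exactly once
    covered: dict[tuple[int, int], int] = {}
    for wall in mesh.walls.values():
        if wall.rest_length <= 0:
            issues.append(f"wall {wall.id}: rest_length must be positive")
        if wall.cell_a not in mesh.cells:
            issues.append(f"wall {wall.id}: unknown cell_a {wall.cell_a}")
            continue
        if wall.cell_b != BOUNDARY and wall.cell_b not in mesh.cells:
            issues.append(f"wall {wall.id}: unknown cell_b {wall.cell_b}")
            continue
        for a, b in zip(wall.node_path[:-1], wall.node_path[1:]):
            key = (a, b) if a < b else (b, a)
            if key in covered:
                issues.append(f"wall {wall.id}: edge {key} already covered by "
                              f"wall {covered[key]}")
            covered[key] = wall.id
            owners = edge_cells.get(key, [])
            expected = {wall.cell_a} if wall.is_boundary else {wall.cell_a, wall.cell_b}
            if set(owners) != expected:
                issues.append(f"wall {wall.id}: edge {key} adjacency mismatch "
                              f"(rings say {owners})")
        if not _path_in_ring(wall.node_path, mesh.cells[wall.cell_a].node_ids):
            issues.append(f"wall {wall.id}: node_path not contiguous in cell_a ring")
        if wall.cell_b != BOUNDARY and not _path_in_ring(
                list(reversed(wall.node_path)), mesh.cells[wall.cell_b].node_ids):
            issues.append(f"wall {wall.id}: node_path not contiguous in cell_b ring")
    for edge in edge_cells:
        if edge not in covered:
            issues.append(f"edge {edge}: not covered by any wall")
    return issues


def generate_grid_tissue(n_rows: int, n_cols: int, cell_size: float = 1.0,
                         n_chemicals: int = 1) -> TissueMesh:
    """Rectangular tissue of square cells — the standard synthetic fixture.

    Each original cell side is one wall: interior sides become internal walls
    shared by the two neighbors, outer sides become boundary walls. Rest
    lengths start at the actual lengths and all chemical amounts at zero.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    mesh = TissueMesh(n_chemicals)
    s = float(cell_size)
    node_id = {}
    for r in range(n_rows + 1):
        for c in range(n_cols + 1):
            boundary = r in (0, n_rows) or c in (0, n_cols)
            node = mesh.add_node(c * s, r * s, at_boundary=boundary)
            node_id[(r, c)] = node.id

    cell_id = {}
    for r in range(n_rows):
        for c in range(n_cols):
            ring = [node_id[(r, c)], node_id[(r, c + 1)],
                    node_id[(r + 1, c + 1)], node_id[(r + 1, c)]]
            cell = mesh.add_cell(ring, target_area=s * s)
            cell_id[(r, c)] = cell.id

    for r in range(n_rows):
        for c in range(n_cols):
            cid = cell_id[(r, c)]
            # bottom side (node order follows this cell's CCW ring)
            if r == 0:
                mesh.add_wall(cid, BOUNDARY, [node_id[(r, c)], node_id[(r, c + 1)]])
            # right side
            if c == n_cols - 1:
                mesh.add_wall(cid, BOUNDARY,
                              [node_id[(r, c + 1)], node_id[(r + 1, c + 1)]])
            else:
                mesh.add_wall(cid, cell_id[(r, c + 1)],
                              [node_id[(r, c + 1)], node_id[(r + 1, c + 1)]])
            # top side
            if r == n_rows - 1:
                mesh.add_wall(cid, BOUNDARY,
                              [node_id[(r + 1, c + 1)], node_id[(r + 1, c)]])
            else:
                mesh.add_wall(cid, cell_id[(r + 1, c)],
                              [node_id[(r + 1, c + 1)], node_id[(r + 1, c)]])
            # left side
            if c == 0:
                mesh.add_wall(cid, BOUNDARY, [node_id[(r + 1, c)], node_id[(r, c)]])
    return mesh
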
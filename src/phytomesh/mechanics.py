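"""Monte Carlo cell mechanics.

The fast elastic response of the tissue is modeled by minimizing a
generalized energy function (Hamiltonian) over node positions with
Metropolis Monte Carlo sampling. Four Hamiltonians are available:

``plain``
    H = lambda_A * sum_cells (a - A_T)^2 + lambda_M * sum_edges (l - L_T)^2
    (absolute target-area deviation plus a spring term on every unique
    polygon edge with a single global target length).
``modified``
    As ``plain`` but the area deviation is relative, ((a - A_T)/a)^2, so
    large cells do not dominate the energy.
``elastic_wall``
    The edge-spring term is replaced by a per-wall elastic energy
    (stiffness/2) * l0 * (l/l0 - 1)^2 with individual stiffness and
    variable rest length l0.
``maxwell``
    The target-area constraint is replaced by a turgor-pressure work term:
    H = -sum_cells P_t * a + (E*h/2) * sum_walls l0 * (l/l0 - 1)^2.

One *MC step* attempts a random displacement of every non-fixed node once,
in a fresh random permutation. Equilibration repeats MC steps until
-sum(accepted dE) < E_th (or a sliding-window criterion is met).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace

import numpy as np

from .mesh import GeometryError, TissueMesh, polygon_area, ring_is_simple

HAMILTONIANS = ("plain", "modified", "elastic_wall", "maxwell")

#: Returned by delta_energy when a move would break cell geometry; the
#: Metropolis rule rejects it at every temperature.
MOVE_INVALID = math.inf


@dataclass
class MechParams:
    """Parameters of the mechanical model.

    Units are the simulation's arbitrary energy/length system: ``lambda_area``
    is energy/area^2 (``plain``) or plain energy (``modified``),
    ``lambda_length`` energy/length^2, ``turgor_pressure`` energy/area,
    ``elastic_modulus`` energy/area, ``temperature`` energy.
    """

    hamiltonian: str = "plain"
    lambda_area: float = 1.0
    lambda_length: float = 1.0
    target_edge_length: float = 1.0
    turgor_pressure: float = 1.0
    elastic_modulus: float = 1.0
    wall_thickness: float = 1.0
    temperature: float = 0.01
    step_amplitude: float = 0.05
    energy_threshold: float = 1e-3   # E_th of the -sum(dE) < E_th criterion
    max_mc_steps: int = 100
    termination: str = "threshold"   # or "sliding_window"
    window_size: int = 10
    window_tol: float = 1e-3

    def __post_init__(self):
        if self.hamiltonian not in HAMILTONIANS:
            raise ValueError(f"unknown hamiltonian {self.hamiltonian!r}; "
                             f"choose from {HAMILTONIANS}")

    def copy(self) -> "MechParams":
        return replace(self)


# ---------------------------------------------------------------------------
# energy


def _area_term(area: float, target: float, params: MechParams) -> float:
    if params.hamiltonian == "plain" or params.hamiltonian == "elastic_wall":
        return params.lambda_area * (area - target) ** 2
    if params.hamiltonian == "modified":
        if area == 0:
            raise GeometryError("modified Hamiltonian undefined for zero-area cell")
        return params.lambda_area * ((area - target) / area) ** 2
    # maxwell: turgor work term
    return -params.turgor_pressure * area


def _wall_term(length: float, rest: float, stiffness: float,
               params: MechParams) -> float:
    if params.hamiltonian == "elastic_wall":
        k = stiffness
    else:  # maxwell
        k = params.elastic_modulus * params.wall_thickness
    return 0.5 * k * rest * (length / rest - 1.0) ** 2


def total_energy(mesh: TissueMesh, params: MechParams) -> float:
    """Hamiltonian of the whole tissue configuration."""
    h = 0.0
    for cid, cell in mesh.cells.items():
        h += _area_term(mesh.cell_area(cid), cell.target_area, params)
    if params.hamiltonian in ("plain", "modified"):
        for a, b in mesh.unique_edges():
            h += params.lambda_length * (
                mesh.edge_length(a, b) - params.target_edge_length) ** 2
    else:
        for wid, wall in mesh.walls.items():
            h += _wall_term(mesh.wall_length(wid), wall.rest_length,
                            wall.stiffness, params)
    return h


def _local_energy(mesh: TissueMesh, params: MechParams, cell_ids, edges, wall_ids):
    h = 0.0
    for cid in cell_ids:
        h += _area_term(mesh.cell_area(cid), mesh.cells[cid].target_area, params)
    if params.hamiltonian in ("plain", "modified"):
        for a, b in edges:
            h += params.lambda_length * (
                mesh.edge_length(a, b) - params.target_edge_length) ** 2
    else:
        for wid in wall_ids:
            wall = mesh.walls[wid]
            h += _wall_term(mesh.wall_length(wid), wall.rest_length,
                            wall.stiffness, params)
    return h


def _incident(mesh: TissueMesh, node_id: int):
    """Cells, unique edges, and walls whose energy depends on a node."""
    cell_ids = [cid for cid, cell in mesh.cells.items()
                if node_id in cell.node_ids]
    edges = set()
    for cid in cell_ids:
        for a, b in mesh.cell_edges(cid):
            if node_id in (a, b):
                edges.add((a, b) if a < b else (b, a))
    wall_ids = [wid for wid, w in mesh.walls.items() if node_id in w.node_path]
    return cell_ids, edges, wall_ids


def _move_keeps_geometry(mesh: TissueMesh, cell_ids) -> bool:
    for cid in cell_ids:
        pts = mesh.cell_polygon(cid)
        if not ring_is_simple(pts) or polygon_area(pts) <= 0:
            return False
    return True


def delta_energy(mesh: TissueMesh, node_id: int, displacement,
                 params: MechParams) -> float:
    """Energy change of displacing one node, from local terms only.

    Matches the full ``H_after - H_before`` recomputation to floating-point
    accuracy because only terms incident to the node change. Returns
    :data:`MOVE_INVALID` (+inf) when the move would make an incident cell
    self-intersecting or non-positive in area.
    """
    node = mesh.nodes[node_id]
    if node.fixed:
        raise ValueError(f"node {node_id} is fixed")
    dx, dy = float(displacement[0]), float(displacement[1])
    cell_ids, edges, wall_ids = _incident(mesh, node_id)
    before = _local_energy(mesh, params, cell_ids, edges, wall_ids)
    node.x += dx
    node.y += dy
    try:
        if not _move_keeps_geometry(mesh, cell_ids):
            return MOVE_INVALID
        after = _local_energy(mesh, params, cell_ids, edges, wall_ids)
    finally:
        node.x -= dx
        node.y -= dy
    return after - before


# ---------------------------------------------------------------------------
# sampling


def propose_displacement(rng: np.random.Generator, step_amplitude: float):
    """Random displacement with components uniform in [-amplitude, amplitude]."""
    if step_amplitude < 0:
        raise ValueError("step_amplitude must be >= 0")
    return rng.uniform(-step_amplitude, step_amplitude, size=2)


def accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis acceptance: downhill always, uphill with exp(-dE/T)."""
    if delta_e <= 0:
        return True
    if temperature <= 0 or not math.isfinite(delta_e):
        return False
    return rng.random() < math.exp(-delta_e / temperature)


def monte_carlo_step(mesh: TissueMesh, params: MechParams,
                     rng: np.random.Generator) -> float:
    """One MC step: attempt to displace every non-fixed node once.

    Nodes are visited in a fresh random permutation; accepted moves are
    applied immediately. Returns the sum of accepted energy changes.
    """
    movable = sorted(nid for nid, n in mesh.nodes.items() if not n.fixed)
    order = rng.permutation(len(movable))
    accepted_sum = 0.0
    for idx in order:
        nid = movable[idx]
        disp = propose_displacement(rng, params.step_amplitude)
        de = delta_energy(mesh, nid, disp, params)
        if accept(de, params.temperature, rng):
            mesh.nodes[nid].x += float(disp[0])
            mesh.nodes[nid].y += float(disp[1])
            accepted_sum += de
    return accepted_sum


def equilibrate(mesh: TissueMesh, params: MechParams,
                rng: np.random.Generator):
    """Repeat MC steps until the termination criterion is met.

    Threshold mode stops when -sum(accepted dE) < E_th; sliding-window mode
    stops when the mean of |sum(accepted dE)| over the last ``window_size``
    steps drops below ``window_tol``. Returns ``(n_steps, converged)``.
    """
    window: deque[float] = deque(maxlen=params.window_size)
    for step in range(1, params.max_mc_steps + 1):
        s = monte_carlo_step(mesh, params, rng)
        if params.termination == "threshold":
            if -s < params.energy_threshold:
                return step, True
        elif params.termination == "sliding_window":
            window.append(abs(s))
            if len(window) == params.window_size and \
                    sum(window) / len(window) < params.window_tol:
                return step, True
        else:
            raise ValueError(f"unknown termination mode {params.termination!r}")
    return params.max_mc_steps, False
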
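"""Slow-phase dynamics: reactions, wall transport, and housekeep rules.

During the slow phase of a simulation step the per-cell chemical amounts
evolve under an assembled ODE system: intracellular reactions (default:
constant areal production with first-order decay), passive transport across
internal walls (flux P * l * (C_j - C_i), conductance proportional to the
shared wall length), and boundary transport against fixed external
concentrations. Geometry is frozen during the slice.

Housekeep rules run once per simulation step and update slow properties:
target-area growth above a concentration threshold, irreversible elastic
wall yielding, and viscous (Maxwell) rest-length relaxation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .mesh import TissueMesh


class ConfigurationError(ValueError):
    """Inconsistent chemistry/boundary configuration."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the failing state."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


@dataclass
class ChemistryParams:
    """Reaction/transport parameters, one entry per chemical species.

    ``production_rates`` are areal rates (amount * area^-1 * time^-1);
    ``decay_rates`` first-order constants (time^-1); ``permeability`` the
    passive wall permeability (length * time^-1). ``production_by_type``
    overrides the production vector for specific cell types.
    """

    production_rates: np.ndarray = field(default_factory=lambda: np.zeros(1))
    decay_rates: np.ndarray = field(default_factory=lambda: np.zeros(1))
    permeability: np.ndarray = field(default_factory=lambda: np.ones(1))
    boundary_permeability: np.ndarray | None = None
    production_by_type: dict = field(default_factory=dict)
    dt: float = 0.1
    solver_rel_tol: float = 1e-8
    solver_abs_tol: float = 1e-10

    def __post_init__(self):
        self.production_rates = np.atleast_1d(
            np.asarray(self.production_rates, dtype=float))
        self.decay_rates = np.atleast_1d(np.asarray(self.decay_rates, dtype=float))
        self.permeability = np.atleast_1d(np.asarray(self.permeability, dtype=float))
        if self.boundary_permeability is not None:
            self.boundary_permeability = np.atleast_1d(
                np.asarray(self.boundary_permeability, dtype=float))
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")

    def production_for(self, cell_type: int) -> np.ndarray:
        return np.asarray(self.production_by_type.get(cell_type,
                                                      self.production_rates))

    def boundary_perm(self) -> np.ndarray:
        return (self.permeability if self.boundary_permeability is None
                else self.boundary_permeability)

    def copy(self) -> "ChemistryParams":
        return replace(
            self,
            production_rates=self.production_rates.copy(),
            decay_rates=self.decay_rates.copy(),
            permeability=self.permeability.copy(),
            boundary_permeability=(None if self.boundary_permeability is None
                                   else self.boundary_permeability.copy()),
            production_by_type={k: np.asarray(v, dtype=float).copy()
                                for k, v in self.production_by_type.items()},
        )


@dataclass
class HousekeepParams:
    growth_rate: float = 0.1            # fractional target-area increase per step
    growth_threshold: float = 1.0       # trigger concentration theta
    yield_ratio: float = 1.5            # wall yields when l/l0 exceeds this
    yield_increment: float = 0.1        # fractional rest-length increase
    maxwell_tau: float = 10.0           # rest-length relaxation time

    def __post_init__(self):
        if self.yield_ratio <= 1:
            raise ConfigurationError("yield_ratio must exceed 1")
        if self.maxwell_tau <= 0:
            raise ConfigurationError("maxwell_tau must be positive")

    def copy(self) -> "HousekeepParams":
        return replace(self)


def default_reaction(cell, area: float, amounts: np.ndarray,
                     params: ChemistryParams) -> np.ndarray:
    """dQ_c/dt = s_c * a - k_c * Q_c (areal production, first-order decay)."""
    return params.production_for(cell.cell_type) * area \
        - params.decay_rates * amounts


def reaction_rates(cell, mesh: TissueMesh, params: ChemistryParams,
                   reaction=None) -> np.ndarray:
    """Intracellular amount derivatives for one cell at its current state."""
    area = mesh.cell_area(cell.id)
    fn = reaction or default_reaction
    return np.asarray(fn(cell, area, cell.chem_amounts, params), dtype=float)


# ---------------------------------------------------------------------------
# ODE assembly


class _OdeSystem:
    """Frozen-geometry right-hand side of the slow-phase ODE."""

    def __init__(self, mesh: TissueMesh, params: ChemistryParams,
                 boundary_conditions=None, virtual_conditions=None,
                 reaction=None):
        self.mesh = mesh
        self.params = params
        self.reaction = reaction or default_reaction
        self.cell_ids = sorted(cid for cid, c in mesh.cells.items() if c.alive)
        self.index = {cid: k for k, cid in enumerate(self.cell_ids)}
        self.n_chem = mesh.n_chemicals
        self.areas = np.array([mesh.cell_area(cid) for cid in self.cell_ids])
        self.cells = [mesh.cells[cid] for cid in self.cell_ids]

        ia, ib, wl = [], [], []
        for wid, wall in mesh.walls.items():
            if wall.is_boundary:
                continue
            if wall.cell_a in self.index and wall.cell_b in self.index:
                ia.append(self.index[wall.cell_a])
                ib.append(self.index[wall.cell_b])
                wl.append(mesh.wall_length(wid))
        self.wall_a = np.array(ia, dtype=int)
        self.wall_b = np.array(ib, dtype=int)
        self.wall_len = np.array(wl, dtype=float)

        self.bc_cell, self.bc_len, self.bc_ext = [], [], []
        for wid, c_ext in (boundary_conditions or {}).items():
            wall = mesh.walls[wid]
            if not wall.is_boundary:
                raise ConfigurationError(
                    f"boundary condition on internal wall {wid}")
            self.bc_cell.append(self.index[wall.cell_a])
            self.bc_len.append(mesh.wall_length(wid))
            self.bc_ext.append(np.broadcast_to(
                np.asarray(c_ext, dtype=float), (self.n_chem,)).copy())
        self.bc_cell = np.array(self.bc_cell, dtype=int)
        self.bc_len = np.array(self.bc_len, dtype=float)
        self.bc_ext = (np.array(self.bc_ext)
                       if self.bc_ext else np.empty((0, self.n_chem)))

        # virtual interfaces: (cell_id, chemical, external conc, conductance)
        self.vc = []
        for cell_id, chem, c_ext, g in (virtual_conditions or []):
            if cell_id not in self.index:
                raise ConfigurationError(f"virtual condition on unknown cell "
                                         f"{cell_id}")
            self.vc.append((self.index[cell_id], int(chem),
                            float(c_ext), float(g)))

    def initial_amounts(self) -> np.ndarray:
        return np.array([c.chem_amounts for c in self.cells]).reshape(-1)

    def write_back(self, y: np.ndarray):
        q = y.reshape(len(self.cells), self.n_chem)
        q = np.where((q < 0) & (q > -1e-9), 0.0, q)
        for cell, amounts in zip(self.cells, q):
            cell.chem_amounts = amounts.copy()

    def derivatives(self, y: np.ndarray) -> np.ndarray:
        q = y.reshape(len(self.cells), self.n_chem)
        conc = q / self.areas[:, None]
        dq = np.zeros_like(q)
        for k, cell in enumerate(self.cells):
            dq[k] += self.reaction(cell, self.areas[k], q[k], self.params)
        if self.wall_a.size:
            flux = (self.params.permeability[None, :] * self.wall_len[:, None]
                    * (conc[self.wall_b] - conc[self.wall_a]))
            np.add.at(dq, self.wall_a, flux)
            np.subtract.at(dq, self.wall_b, flux)
        if self.bc_cell.size:
            perm = self.params.boundary_perm()
            flux = (perm[None, :] * self.bc_len[:, None]
                    * (self.bc_ext - conc[self.bc_cell]))
            np.add.at(dq, self.bc_cell, flux)
        for k, chem, c_ext, g in self.vc:
            dq[k, chem] += g * (c_ext - conc[k, chem])
        return dq.reshape(-1)

    def __call__(self, t, y):
        return self.derivatives(y)


def transport_rates(mesh: TissueMesh, params: ChemistryParams) -> dict:
    """Per-cell amount derivatives from internal wall transport only."""
    sys = _OdeSystem(mesh, params)
    sys.reaction = lambda cell, a, q, p: np.zeros(sys.n_chem)
    sys.vc = []
    dq = sys.derivatives(sys.initial_amounts()).reshape(-1, sys.n_chem)
    return {cid: dq[k] for cid, k in sys.index.items()}


def boundary_transport_rates(mesh: TissueMesh, boundary_conditions,
                             params: ChemistryParams) -> dict:
    """Per-cell amount derivatives from boundary transport only."""
    sys = _OdeSystem(mesh, params, boundary_conditions=boundary_conditions)
    sys.reaction = lambda cell, a, q, p: np.zeros(sys.n_chem)
    sys.wall_a = sys.wall_b = np.array([], dtype=int)
    sys.wall_len = np.array([])
    dq = sys.derivatives(sys.initial_amounts()).reshape(-1, sys.n_chem)
    return {cid: dq[k] for cid, k in sys.index.items()}


def assembled_derivatives(mesh: TissueMesh, params: ChemistryParams,
                          boundary_conditions=None, virtual_conditions=None,
                          reaction=None) -> dict:
    """Full right-hand side (reaction + transport + boundary) at the
    current state; useful for mass-balance audits."""
    sys = _OdeSystem(mesh, params, boundary_conditions, virtual_conditions,
                     reaction)
    dq = sys.derivatives(sys.initial_amounts()).reshape(-1, sys.n_chem)
    return {cid: dq[k] for cid, k in sys.index.items()}


def integrate_slice(mesh: TissueMesh, params: ChemistryParams,
                    boundary_conditions=None, duration: float = None,
                    virtual_conditions=None, reaction=None) -> TissueMesh:
    """Advance all chemical amounts over one time slice.

    Solves the assembled ODE system with an adaptive Runge-Kutta solver at
    the configured tolerances. Geometry is untouched.
    """
    if duration is None:
        duration = params.dt
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    sys = _OdeSystem(mesh, params, boundary_conditions, virtual_conditions,
                     reaction)
    if not sys.cell_ids or sys.n_chem == 0:
        return mesh
    y0 = sys.initial_amounts()
    sol = solve_ivp(sys, (0.0, duration), y0, method="RK45",
                    rtol=params.solver_rel_tol, atol=params.solver_abs_tol)
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}", state=y0)
    sys.write_back(sol.y[:, -1])
    return mesh


# ---------------------------------------------------------------------------
# housekeep rules (once per simulation step)


def housekeep_geometric(mesh: TissueMesh, hk: HousekeepParams,
                        trigger_chemical: int = 0, enabled: bool = True,
                        growing_flag: str | None = None) -> TissueMesh:
    """Grow target areas of cells whose trigger concentration reaches theta.

    For each alive cell with C_trigger >= growth_threshold the target area
    is scaled by (1 + growth_rate). When ``growing_flag`` is given, each
    cell's flag of that name records whether it grew this step (used by
    growth-gated chemistry components).
    """
    if not enabled:
        if growing_flag:
            for cell in mesh.cells.values():
                cell.flags[growing_flag] = False
        return mesh
    for cid, cell in mesh.cells.items():
        if not cell.alive:
            continue
        if trigger_chemical < len(cell.chem_amounts):
            conc = cell.chem_amounts[trigger_chemical] / mesh.cell_area(cid)
        else:
            conc = 0.0  # chemistry-free model: grow iff the threshold is zero
        grew = conc >= hk.growth_threshold
        if grew:
            cell.target_area *= (1.0 + hk.growth_rate)
        if growing_flag:
            cell.flags[growing_flag] = bool(grew)
    return mesh


def housekeep_elastic_wall(mesh: TissueMesh, hk: HousekeepParams) -> TissueMesh:
    """Irreversible wall yielding: l0 grows by a fixed fraction whenever the
    actual length exceeds yield_ratio * l0. Rest lengths never shrink."""
    for wid, wall in mesh.walls.items():
        if mesh.wall_length(wid) / wall.rest_length > hk.yield_ratio:
            wall.rest_length *= (1.0 + hk.yield_increment)
    return mesh


def housekeep_maxwell(mesh: TissueMesh, hk: HousekeepParams,
                      dt: float) -> TissueMesh:
    """Viscous rest-length relaxation dl0/dt = (l - l0)/tau over one step,
    integrated in closed form: l0 <- l + (l0 - l) * exp(-dt/tau)."""
    decay = math.exp(-dt / hk.maxwell_tau)
    for wid, wall in mesh.walls.items():
        length = mesh.wall_length(wid)
        wall.rest_length = length + (wall.rest_length - length) * decay
    return mesh
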
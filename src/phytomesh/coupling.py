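"""Coupling two tissue simulations through boundary-condition exchange.

Two simulations advance in lockstep. Each simulation time step is divided
into ``n_slices`` time slices; before (or after) each slice the coupler
copies the current concentration of every linked partner cell into the
other model's boundary conditions, where it acts as a frozen external
(Dirichlet) concentration with conductance ``g`` for the duration of the
slice. After all slices both models run their mechanical phases
independently.

The frozen-partner scheme conserves mass only approximately; the error
shrinks as ``n_slices`` grows. A strictly conservative variant
(``conservative=True``) integrates both models' chemistry as one joint ODE
with live pairwise link fluxes, for comparison.

The same module exposes the external-driver protocol: a master script can
read coupled-cell concentrations (:func:`driver_get_concentrations`) and
install frozen external concentrations (:func:`driver_set_boundary`)
between time steps of a simulation it owns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import engine as engine_mod
from .chemistry import ConfigurationError, IntegrationError, _OdeSystem
from .engine import SimState, _ORDERINGS, _PHASES, _chemistry_phase


class CouplingSpecError(ValueError):
    """A coupling link references a cell or chemical that does not exist."""


@dataclass
class CouplingLink:
    """One cross-model link: cell_a (model A) <-> cell_b (model B).

    ``conductance`` is the effective P*l of the virtual shared interface
    (area/time): flux into cell_a is g * (C_b - C_a) and vice versa.
    """

    cell_a: int
    cell_b: int
    chemical: int = 0
    conductance: float = 1.0

    def __post_init__(self):
        if self.conductance < 0:
            raise CouplingSpecError("conductance must be >= 0")


@dataclass
class CouplingSpec:
    links: list = field(default_factory=list)
    n_slices: int = 1
    exchange_at: str = "slice_start"   # or "slice_end"
    conservative: bool = False

    def __post_init__(self):
        if self.n_slices < 1:
            raise CouplingSpecError("n_slices must be >= 1")
        if self.exchange_at not in ("slice_start", "slice_end"):
            raise CouplingSpecError(f"unknown exchange_at {self.exchange_at!r}")


def _check_links(sim_a: SimState, sim_b: SimState, spec: CouplingSpec):
    for link in spec.links:
        if link.cell_a not in sim_a.mesh.cells:
            raise CouplingSpecError(f"link references unknown cell {link.cell_a} "
                                    f"in model A")
        if link.cell_b not in sim_b.mesh.cells:
            raise CouplingSpecError(f"link references unknown cell {link.cell_b} "
                                    f"in model B")
        if link.chemical >= min(sim_a.mesh.n_chemicals, sim_b.mesh.n_chemicals):
            raise CouplingSpecError(f"link chemical {link.chemical} out of range")


def exchange_boundaries(sim_a: SimState, sim_b: SimState,
                        spec: CouplingSpec) -> None:
    """Refresh both models' coupling boundary conditions from current state.

    For every link, model A sees the partner cell's concentration as a
    frozen external concentration on a virtual interface of conductance g
    (and symmetrically for B). Values stay frozen until the next exchange.
    """
    _check_links(sim_a, sim_b, spec)
    cond_a, cond_b = [], []
    for link in spec.links:
        c_b = sim_b.mesh.concentration(link.cell_b, link.chemical)
        c_a = sim_a.mesh.concentration(link.cell_a, link.chemical)
        cond_a.append((link.cell_a, link.chemical, c_b, link.conductance))
        cond_b.append((link.cell_b, link.chemical, c_a, link.conductance))
    sim_a.coupling_conditions = cond_a
    sim_b.coupling_conditions = cond_b


def _joint_chemistry(sim_a: SimState, sim_b: SimState, spec: CouplingSpec,
                     duration: float):
    """Strictly conservative variant: one joint ODE with live link fluxes."""
    systems = []
    for sim in (sim_a, sim_b):
        comp = sim.components["cell_chemistry"]
        comp.update_gates(sim.mesh, sim.spec)
        systems.append(_OdeSystem(sim.mesh, sim.spec.chem,
                                  boundary_conditions=sim.boundary_conditions,
                                  virtual_conditions=sim.driver_conditions,
                                  reaction=comp.reaction))
    sys_a, sys_b = systems
    na = sys_a.initial_amounts().size
    y0 = np.concatenate([sys_a.initial_amounts(), sys_b.initial_amounts()])
    link_idx = [(sys_a.index[l.cell_a], sys_b.index[l.cell_b], l.chemical,
                 l.conductance) for l in spec.links]

    def rhs(t, y):
        dy = np.concatenate([sys_a.derivatives(y[:na]),
                             sys_b.derivatives(y[na:])])
        qa = y[:na].reshape(-1, sys_a.n_chem)
        qb = y[na:].reshape(-1, sys_b.n_chem)
        da = dy[:na].reshape(-1, sys_a.n_chem)
        db = dy[na:].reshape(-1, sys_b.n_chem)
        for ka, kb, chem, g in link_idx:
            flux = g * (qb[kb, chem] / sys_b.areas[kb]
                        - qa[ka, chem] / sys_a.areas[ka])
            da[ka, chem] += flux
            db[kb, chem] -= flux
        return dy

    sol = solve_ivp(rhs, (0.0, duration), y0, method="RK45",
                    rtol=sim_a.spec.chem.solver_rel_tol,
                    atol=sim_a.spec.chem.solver_abs_tol)
    if not sol.success:
        raise IntegrationError(f"joint ODE solver failed: {sol.message}")
    sys_a.write_back(sol.y[:na, -1])
    sys_b.write_back(sol.y[na:, -1])


def coupled_time_step(sim_a: SimState, sim_b: SimState,
                      spec: CouplingSpec) -> tuple[SimState, SimState]:
    """One lockstep time step of two coupled simulations.

    The chemistry of both models advances over ``n_slices`` sub-intervals of
    the shared dt with boundary conditions re-exchanged each slice; then
    each model runs its housekeep/division/insertion/mechanics phases
    individually.
    """
    if sim_a.spec.dt != sim_b.spec.dt:
        raise ConfigurationError("coupled simulations must share dt")
    _check_links(sim_a, sim_b, spec)
    for sim in (sim_a, sim_b):
        sim.apply_pending()

    dt = sim_a.spec.dt
    if spec.conservative:
        _joint_chemistry(sim_a, sim_b, spec, dt)
    else:
        slice_dt = dt / spec.n_slices
        for _ in range(spec.n_slices):
            if spec.exchange_at == "slice_start":
                exchange_boundaries(sim_a, sim_b, spec)
            _chemistry_phase(sim_a, duration=slice_dt)
            _chemistry_phase(sim_b, duration=slice_dt)
            if spec.exchange_at == "slice_end":
                exchange_boundaries(sim_a, sim_b, spec)

    for sim in (sim_a, sim_b):
        evolver = sim.spec.components.get("time_evolver", "mechanics_last")
        for phase in _ORDERINGS[evolver]:
            if phase == "chemistry":
                continue  # chemistry already ran in slices
            _PHASES[phase](sim)
        sim.step_index += 1
        sim.sim_time += dt
    return sim_a, sim_b


def run_coupled(sim_a: SimState, sim_b: SimState, spec: CouplingSpec,
                n_steps: int, observers=()) -> tuple[SimState, SimState]:
    for _ in range(n_steps):
        coupled_time_step(sim_a, sim_b, spec)
        for obs in observers:
            obs(sim_a.step_index, sim_a.sim_time, sim_a, sim_b)
    return sim_a, sim_b


# ---------------------------------------------------------------------------
# external driver protocol


def driver_get_concentrations(sim: SimState, cell_ids, chemical: int):
    """Read-only concentration snapshot, in the order of the requested ids."""
    out = []
    for cid in cell_ids:
        if cid not in sim.mesh.cells:
            raise LookupError(f"unknown cell id {cid}")
        out.append(sim.mesh.concentration(cid, chemical))
    return out


def driver_set_boundary(sim: SimState, assignments) -> SimState:
    """Install frozen external concentrations for the next time step.

    ``assignments`` is a list of (cell_id, chemical, external_concentration,
    conductance). The call replaces any previous driver assignments
    (idempotent per step); an empty list restores no-flux boundaries.
    """
    conditions = []
    for cid, chem, c_ext, g in assignments:
        if cid not in sim.mesh.cells:
            raise LookupError(f"unknown cell id {cid}")
        conditions.append((int(cid), int(chem), float(c_ext), float(g)))
    sim.driver_conditions = conditions
    return sim


# ---------------------------------------------------------------------------
# demo drivers used by tests, the acceptance script and the docs


def facing_boundary_links(sim_a: SimState, sim_b: SimState, chemical=0,
                          conductance=1.0, column_a=None, column_b=0):
    """Link the right-edge cells of grid A to the left-edge cells of grid B.

    Grid fixtures number cells row-major; this pairs facing boundary cells
    of two equally tall grids, the layout of the producer/receiver demo.
    """
    def grid_shape(sim):
        xs = sorted({round(n.x, 9) for n in sim.mesh.nodes.values()})
        ys = sorted({round(n.y, 9) for n in sim.mesh.nodes.values()})
        return len(ys) - 1, len(xs) - 1  # rows, cols

    rows_a, cols_a = grid_shape(sim_a)
    rows_b, cols_b = grid_shape(sim_b)
    if rows_a != rows_b:
        raise CouplingSpecError("grids must have equal row counts")
    ca = cols_a - 1 if column_a is None else column_a
    ids_a = sorted(sim_a.mesh.cells)
    ids_b = sorted(sim_b.mesh.cells)
    links = []
    for r in range(rows_a):
        links.append(CouplingLink(ids_a[r * cols_a + ca],
                                  ids_b[r * cols_b + column_b],
                                  chemical, conductance))
    return links


def run_producer_receiver(n_rows=5, n_cols=5, conductance=1.0, n_slices=1,
                          n_steps=100, dt=0.1, seed=0, conservative=False):
    """Producer/receiver pair: grid A produces chemical 0, grid B receives.

    Returns a dict with per-step total amounts in each model and the
    analytic production integral (rate * producer area * time, exact for
    the static producer geometry).
    """
    sim_a = engine_mod.make_demo_sim("coupling_producer", n_rows, n_cols,
                                     seed=seed, dt=dt)
    sim_b = engine_mod.make_demo_sim("coupling_receiver", n_rows, n_cols,
                                     seed=seed + 1, dt=dt)
    links = facing_boundary_links(sim_a, sim_b, chemical=0,
                                  conductance=conductance)
    spec = CouplingSpec(links=links, n_slices=n_slices,
                        conservative=conservative)
    area_a = sim_a.mesh.total_area()
    record = {"step": [], "time": [], "mass_a": [], "mass_b": [],
              "analytic_total": []}

    def observer(step, time, sa, sb):
        record["step"].append(step)
        record["time"].append(time)
        record["mass_a"].append(sum(float(c.chem_amounts[0])
                                    for c in sa.mesh.cells.values()))
        record["mass_b"].append(sum(float(c.chem_amounts[0])
                                    for c in sb.mesh.cells.values()))
        record["analytic_total"].append(1.0 * area_a * time)

    run_coupled(sim_a, sim_b, spec, n_steps, observers=[observer])
    return record


def run_leaf_root_demo(n_steps=300, n_rows=3, n_cols=3, dt=0.1, seed=0,
                       conductance=2.0, stop_threshold=0.3,
                       growth_threshold=1.0, growth_rate=0.05):
    """Leaf-root feedback demo via the external-driver protocol.

    A static leaf produces chemical 0; a master loop carries chemical levels
    between the two simulations each step through driver_get/driver_set.
    The root grows once chemical 0 crosses its threshold and then produces
    chemical 1, which is carried back to the leaf and eventually shuts down
    chemical-0 production, arresting root growth.

    Returns a per-step record (lists) of concentrations, root area and
    target area, and the latched leaf production state.
    """
    leaf = engine_mod.make_demo_sim("leaf", n_rows, n_cols, seed=seed, dt=dt,
                                    stop_threshold=stop_threshold)
    root = engine_mod.make_demo_sim("root", n_rows, n_cols, seed=seed + 1,
                                    dt=dt, growth_threshold=growth_threshold,
                                    growth_rate=growth_rate)
    leaf_cells = sorted(leaf.mesh.cells)
    root_cells = sorted(root.mesh.cells)
    # couple the first boundary cell of each tissue
    lc, rc = leaf_cells[0], root_cells[0]

    record = {"step": [], "leaf_c0": [], "leaf_c1": [], "root_c0": [],
              "root_c1": [], "root_area": [], "root_target_area": [],
              "leaf_producing": []}
    for step in range(1, n_steps + 1):
        # exchange: each model sees the partner cell's current concentration
        c0_root = driver_get_concentrations(root, [rc], 0)[0]
        c1_root = driver_get_concentrations(root, [rc], 1)[0]
        c0_leaf = driver_get_concentrations(leaf, [lc], 0)[0]
        c1_leaf = driver_get_concentrations(leaf, [lc], 1)[0]
        driver_set_boundary(leaf, [(lc, 0, c0_root, conductance),
                                   (lc, 1, c1_root, conductance)])
        driver_set_boundary(root, [(rc, 0, c0_leaf, conductance),
                                   (rc, 1, c1_leaf, conductance)])
        engine_mod.time_step(leaf)
        engine_mod.time_step(root)

        record["step"].append(step)
        record["leaf_c0"].append(np.mean([leaf.mesh.concentration(c, 0)
                                          for c in leaf_cells]))
        record["leaf_c1"].append(np.mean([leaf.mesh.concentration(c, 1)
                                          for c in leaf_cells]))
        record["root_c0"].append(np.mean([root.mesh.concentration(c, 0)
                                          for c in root_cells]))
        record["root_c1"].append(np.mean([root.mesh.concentration(c, 1)
                                          for c in root_cells]))
        record["root_area"].append(root.mesh.total_area())
        record["root_target_area"].append(sum(c.target_area for c in
                                              root.mesh.cells.values()))
        record["leaf_producing"].append(
            not all(c.flags.get("production_stopped")
                    for c in leaf.mesh.cells.values()))
    return record
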
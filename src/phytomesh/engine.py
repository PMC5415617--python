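"""Simulation engine: component registry, model specs, and time stepping.

A *model* is a named selection of components — one per component type
(chemistry, transport, division rule, housekeep rule, Hamiltonian, move
generator, time evolver, ...) — plus numeric parameters. The registry maps
component types and names to implementations; meta-components dispatch to
other registered components of the same type (e.g. a division rule that
picks a sub-rule by cell type).

One simulation time step has two phases: a slow phase (reaction-transport
ODE integration, housekeep rules, cell division, node insertion) and a fast
elastic phase (Monte Carlo equilibration). The ``mechanics_last`` evolver
ends the step with equilibration; the ``chemistry_last`` evolver rotates
the ring so the step ends with the reaction/transport integration instead.
Parameter and component changes queued during a step take effect at the
start of the following step.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from . import chemistry as chem_mod
from . import mechanics as mech_mod
from .mesh import TissueMesh, divide_cell, generate_grid_tissue, split_long_edges

EVOLVERS = ("mechanics_last", "chemistry_last")


class ResolutionError(KeyError):
    """A component name could not be resolved in the registry."""


class CycleError(ValueError):
    """Meta-component references form a cycle."""


class PhaseError(RuntimeError):
    """An error inside one phase of a time step, tagged with the phase name."""

    def __init__(self, phase, original):
        super().__init__(f"phase {phase!r}: {original}")
        self.phase = phase
        self.original = original


# ---------------------------------------------------------------------------
# component implementations

class ChemistryComponent:
    """Intracellular reaction kinetics; gates are refreshed once per step."""

    def update_gates(self, mesh, spec):
        pass

    def reaction(self, cell, area, amounts, params):
        raise NotImplementedError


class NoChemistry(ChemistryComponent):
    def reaction(self, cell, area, amounts, params):
        return np.zeros_like(amounts)


class SourceDecayChemistry(ChemistryComponent):
    """dQ_c/dt = s_c * area - k_c * Q_c."""

    def reaction(self, cell, area, amounts, params):
        return chem_mod.default_reaction(cell, area, amounts, params)


class LeafChemistry(SourceDecayChemistry):
    """Source/decay kinetics whose chemical-0 production latches off.

    Once the concentration of ``stop_chemical`` reaches ``stop_threshold``
    in a cell, that cell permanently stops producing chemical 0 (flag
    ``production_stopped``). The gate is evaluated once per step.
    """

    def update_gates(self, mesh, spec):
        stop_chem = int(spec.component_params.get("stop_chemical", 1))
        theta = float(spec.component_params.get("stop_threshold", 1.0))
        for cid, cell in mesh.cells.items():
            if cell.flags.get("production_stopped"):
                continue
            if cell.chem_amounts[stop_chem] / mesh.cell_area(cid) >= theta:
                cell.flags["production_stopped"] = True

    def reaction(self, cell, area, amounts, params):
        rates = chem_mod.default_reaction(cell, area, amounts, params)
        if cell.flags.get("production_stopped"):
            production = params.production_for(cell.cell_type)
            rates = rates - np.array([production[0]] +
                                     [0.0] * (len(amounts) - 1)) * area
        return rates


class RootChemistry(SourceDecayChemistry):
    """Source/decay kinetics with chemical-1 production gated on growth.

    Production of chemical 1 is active only in cells whose ``growing`` flag
    was set by the geometric-growth housekeep rule this step.
    """

    def reaction(self, cell, area, amounts, params):
        rates = chem_mod.default_reaction(cell, area, amounts, params)
        if not cell.flags.get("growing"):
            production = params.production_for(cell.cell_type)
            mask = np.zeros_like(amounts)
            if len(amounts) > 1:
                mask[1] = production[1]
            rates = rates - mask * area
        return rates


class HousekeepComponent:
    def apply(self, sim):
        pass


class NoHousekeep(HousekeepComponent):
    pass


class GeometricGrowthHousekeep(HousekeepComponent):
    def apply(self, sim):
        trig = int(sim.spec.component_params.get("growth_trigger_chemical", 0))
        chem_mod.housekeep_geometric(sim.mesh, sim.spec.housekeep,
                                     trigger_chemical=trig, enabled=True,
                                     growing_flag="growing")


class ElasticYieldHousekeep(HousekeepComponent):
    def apply(self, sim):
        chem_mod.housekeep_elastic_wall(sim.mesh, sim.spec.housekeep)


class MaxwellHousekeep(HousekeepComponent):
    def apply(self, sim):
        chem_mod.housekeep_maxwell(sim.mesh, sim.spec.housekeep, sim.spec.dt)


class SplitComponent:
    def should_divide(self, cell, mesh, spec) -> bool:
        return False


class NoSplit(SplitComponent):
    pass


class AreaThresholdSplit(SplitComponent):
    """Divide when the cell area reaches division_factor x birth area."""

    def should_divide(self, cell, mesh, spec):
        return mesh.cell_area(cell.id) >= spec.division_factor * cell.base_area


class MetaByTypeSplit(SplitComponent):
    """Meta-component: dispatch the division rule on cell type."""

    def __init__(self, cases: dict, default: SplitComponent):
        self.cases = cases          # cell_type -> SplitComponent
        self.default = default

    def should_divide(self, cell, mesh, spec):
        rule = self.cases.get(cell.cell_type, self.default)
        return rule.should_divide(cell, mesh, spec)


def color_by_type(cell, mesh):
    palette = [(0.55, 0.71, 0.0), (0.8, 0.36, 0.36), (0.27, 0.51, 0.71),
               (0.93, 0.79, 0.0)]
    return palette[cell.cell_type % len(palette)]


def color_by_chemical(cell, mesh, scale=1.0):
    if mesh.n_chemicals == 0:
        return (0.5, 0.5, 0.5)
    c0 = min(1.0, cell.chem_amounts[0] / mesh.cell_area(cell.id) / scale)
    c1 = 0.0
    if mesh.n_chemicals > 1:
        c1 = min(1.0, cell.chem_amounts[1] / mesh.cell_area(cell.id) / scale)
    return (c0, 0.2, c1)


class WallChemistryHook:
    """Per-side wall species dynamics hook; the built-in has zero kinetics."""

    def rates(self, wall, mesh):
        return np.zeros_like(wall.transporters_a), np.zeros_like(wall.transporters_b)


#: registry: component type -> name -> zero-arg factory
REGISTRY: dict[str, dict] = {
    "cell_chemistry": {
        "none": NoChemistry,
        "source_decay": SourceDecayChemistry,
        "leaf": LeafChemistry,
        "root": RootChemistry,
    },
    "cell_color": {
        "by_type": lambda: color_by_type,
        "by_chemical": lambda: color_by_chemical,
    },
    "cell_daughters": {
        "proportional": lambda: "proportional",
    },
    "cell_housekeep": {
        "none": NoHousekeep,
        "geometric_growth": GeometricGrowthHousekeep,
        "elastic_yield": ElasticYieldHousekeep,
        "maxwell_relax": MaxwellHousekeep,
    },
    "cell_split": {
        "none": NoSplit,
        "area_threshold": AreaThresholdSplit,
    },
    "cell2cell_transport": {
        "passive": lambda: "passive",
        "none": lambda: "none",
    },
    "cell2cell_transport_boundary": {
        "passive": lambda: "passive",
        "none": lambda: "none",
    },
    "hamiltonian": {name: (lambda n=name: n) for name in mech_mod.HAMILTONIANS},
    "move_generator": {
        "uniform": lambda: mech_mod.propose_displacement,
    },
    "time_evolver": {name: (lambda n=name: n) for name in EVOLVERS},
    "wall_chemistry": {
        "none": WallChemistryHook,
    },
}

DEFAULT_COMPONENTS = {
    "cell_chemistry": "source_decay",
    "cell_color": "by_chemical",
    "cell_daughters": "proportional",
    "cell_housekeep": "none",
    "cell_split": "none",
    "cell2cell_transport": "passive",
    "cell2cell_transport_boundary": "passive",
    "hamiltonian": "plain",
    "move_generator": "uniform",
    "time_evolver": "mechanics_last",
    "wall_chemistry": "none",
}


# ---------------------------------------------------------------------------
# model spec and state


@dataclass
class ModelSpec:
    """Component selection plus numeric parameters; fully serializable."""

    components: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENTS))
    mech: mech_mod.MechParams = field(default_factory=mech_mod.MechParams)
    chem: chem_mod.ChemistryParams = field(default_factory=chem_mod.ChemistryParams)
    housekeep: chem_mod.HousekeepParams = field(
        default_factory=chem_mod.HousekeepParams)
    n_chemicals: int = 1
    seed: int = 0
    division_factor: float = 2.0
    division_axis: tuple | None = None   # None -> perpendicular to inertia axis
    target_node_distance: float | None = None
    component_params: dict = field(default_factory=dict)
    meta_definitions: dict = field(default_factory=dict)  # (type,name)->meta dict
    extensions: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return self.chem.dt

    def copy(self) -> "ModelSpec":
        return ModelSpec(
            components=_copy.deepcopy(self.components),
            mech=self.mech.copy(), chem=self.chem.copy(),
            housekeep=self.housekeep.copy(),
            n_chemicals=self.n_chemicals, seed=self.seed,
            division_factor=self.division_factor,
            division_axis=self.division_axis,
            target_node_distance=self.target_node_distance,
            component_params=dict(self.component_params),
            meta_definitions=_copy.deepcopy(self.meta_definitions),
            extensions=dict(self.extensions),
        )


def resolve_component(ctype: str, name, spec: ModelSpec, _stack=None):
    """Resolve a component name (or meta definition) to an implementation."""
    table = REGISTRY.get(ctype)
    if table is None:
        raise ResolutionError(f"unknown component type {ctype!r}")
    if isinstance(name, dict):
        return _build_meta(ctype, name, spec, _stack or [])
    if name in table:
        return table[name]()
    if (ctype, name) in spec.meta_definitions:
        stack = _stack or []
        if (ctype, name) in stack:
            chain = " -> ".join(n for _, n in stack + [(ctype, name)])
            raise CycleError(f"meta-component cycle: {chain}")
        return _build_meta(ctype, spec.meta_definitions[(ctype, name)], spec,
                           stack + [(ctype, name)])
    raise ResolutionError(
        f"unknown {ctype} component {name!r}; valid names: "
        f"{sorted(table) + sorted(n for t, n in spec.meta_definitions if t == ctype)}")


def _build_meta(ctype, meta, spec, stack):
    kind = meta.get("meta")
    if ctype == "cell_split" and kind == "by_type":
        cases = {int(k): resolve_component(ctype, v, spec, stack)
                 for k, v in meta.get("cases", {}).items()}
        default = resolve_component(ctype, meta.get("default", "none"), spec, stack)
        return MetaByTypeSplit(cases, default)
    raise ResolutionError(f"unknown meta-component kind {kind!r} for {ctype}")


def resolve_all(spec: ModelSpec) -> dict:
    return {ctype: resolve_component(ctype, name, spec)
            for ctype, name in spec.components.items()}


class SimState:
    """One steppable simulation: mesh + spec + clock + RNG + pending changes."""

    def __init__(self, mesh: TissueMesh, spec: ModelSpec,
                 rng: np.random.Generator | None = None):
        self.mesh = mesh
        self.spec = spec
        self.step_index = 0
        self.sim_time = 0.0
        self.rng = rng if rng is not None else np.random.default_rng(spec.seed)
        self.pending_changes: list = []
        self.boundary_conditions: dict = {}    # wall id -> external conc vector
        self.driver_conditions: list = []      # (cell, chem, c_ext, g)
        self.coupling_conditions: list = []    # managed by the coupler
        self.components = resolve_all(spec)
        self.last_convergence: tuple | None = None  # (n_mc_steps, converged)

    def queue_change(self, path: str, value):
        """Queue a parameter/component change; applied at the next step start."""
        self.pending_changes.append((path, value))

    def _apply_change(self, path: str, value):
        parts = path.split(".")
        if parts[0] == "components":
            self.spec.components[parts[1]] = value
            self.components = resolve_all(self.spec)
            return
        obj = self.spec
        for p in parts[:-1]:
            obj = getattr(obj, p)
        current = getattr(obj, parts[-1], None)
        if isinstance(current, np.ndarray):
            value = np.broadcast_to(np.asarray(value, dtype=float),
                                    current.shape).copy()
        elif isinstance(current, float):
            value = float(value)
        elif isinstance(current, int) and not isinstance(current, bool):
            value = int(value)
        setattr(obj, parts[-1], value)
        if parts[-1] == "hamiltonian":
            self.spec.components["hamiltonian"] = value
        if path == "components":
            self.components = resolve_all(self.spec)

    def apply_pending(self):
        for path, value in self.pending_changes:
            self._apply_change(path, value)
        self.pending_changes.clear()
        # keep the MechParams Hamiltonian in sync with the component selection
        self.spec.mech.hamiltonian = self.spec.components.get(
            "hamiltonian", self.spec.mech.hamiltonian)

    def virtual_conditions(self):
        return list(self.coupling_conditions) + list(self.driver_conditions)


def build_sim(tissue_file_content: str | tuple, overrides: dict | None = None
              ) -> SimState:
    """Build a ready simulation from tissue-file text (or a (mesh, spec) pair).

    ``overrides`` maps dotted parameter paths (e.g. ``chem.dt`` or
    ``components.cell_split``) to values applied before the RNG is seeded.
    """
    if isinstance(tissue_file_content, tuple):
        mesh, spec = tissue_file_content
    else:
        from .io import read_tissue_xml
        mesh, spec = read_tissue_xml(tissue_file_content)
    sim = SimState(mesh, spec)
    for path, value in (overrides or {}).items():
        sim._apply_change(path, value)
    sim.spec.mech.hamiltonian = sim.spec.components.get(
        "hamiltonian", sim.spec.mech.hamiltonian)
    sim.components = resolve_all(sim.spec)
    sim.rng = np.random.default_rng(sim.spec.seed)
    return sim


# ---------------------------------------------------------------------------
# time stepping


def _chemistry_phase(sim: SimState, duration: float | None = None):
    comp: ChemistryComponent = sim.components["cell_chemistry"]
    comp.update_gates(sim.mesh, sim.spec)
    params = sim.spec.chem
    if sim.spec.components.get("cell2cell_transport") == "none":
        params = params.copy()
        params.permeability = np.zeros_like(params.permeability)
    bc = sim.boundary_conditions
    vc = sim.virtual_conditions()
    if sim.spec.components.get("cell2cell_transport_boundary") == "none":
        bc, vc = {}, []
    chem_mod.integrate_slice(sim.mesh, params, boundary_conditions=bc,
                             duration=duration if duration is not None
                             else sim.spec.dt,
                             virtual_conditions=vc,
                             reaction=comp.reaction)


def _housekeep_phase(sim: SimState):
    sim.components["cell_housekeep"].apply(sim)


def _division_phase(sim: SimState):
    split: SplitComponent = sim.components["cell_split"]
    for cid in sorted(sim.mesh.cells):
        cell = sim.mesh.cells.get(cid)
        if cell is None or not cell.alive:
            continue
        if split.should_divide(cell, sim.mesh, sim.spec):
            divide_cell(sim.mesh, cid, axis=sim.spec.division_axis)


def _insertion_phase(sim: SimState):
    if sim.spec.target_node_distance is not None:
        split_long_edges(sim.mesh, sim.spec.target_node_distance)


def _mechanics_phase(sim: SimState):
    n_steps, converged = mech_mod.equilibrate(sim.mesh, sim.spec.mech, sim.rng)
    sim.last_convergence = (n_steps, converged)


_PHASES = {
    "chemistry": _chemistry_phase,
    "housekeep": _housekeep_phase,
    "division": _division_phase,
    "node_insertion": _insertion_phase,
    "mechanics": _mechanics_phase,
}

_ORDERINGS = {
    # slow processes first, step ends with elastic equilibration
    "mechanics_last": ("chemistry", "housekeep", "division",
                       "node_insertion", "mechanics"),
    # same ring rotated: the step ends with reaction/transport instead
    "chemistry_last": ("housekeep", "division", "node_insertion",
                       "mechanics", "chemistry"),
}


def time_step(sim: SimState) -> SimState:
    """Advance the simulation by one step (in place) and return it."""
    sim.apply_pending()
    evolver = sim.spec.components.get("time_evolver", "mechanics_last")
    if evolver not in _ORDERINGS:
        raise ResolutionError(f"unknown time_evolver {evolver!r}")
    for phase in _ORDERINGS[evolver]:
        try:
            _PHASES[phase](sim)
        except Exception as exc:  # tag errors with the failing phase
            raise PhaseError(phase, exc) from exc
    sim.step_index += 1
    sim.sim_time += sim.spec.dt
    return sim


def run(sim: SimState, n_steps: int, observers=()) -> SimState:
    """Apply ``n_steps`` time steps, invoking observers after each step.

    Observers are callbacks ``(step_index, sim_time, sim)`` used for CSV
    output, probes, etc.; they must not mutate the state.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    for _ in range(n_steps):
        time_step(sim)
        for obs in observers:
            obs(sim.step_index, sim.sim_time, sim)
    return sim


# ---------------------------------------------------------------------------
# built-in demo models


def _static_mech() -> mech_mod.MechParams:
    return mech_mod.MechParams(temperature=0.0, step_amplitude=0.02,
                               energy_threshold=1e-3, max_mc_steps=20)


def model_coupling_producer(**kw) -> ModelSpec:
    """Constant production of chemical 0 (rate 1 per unit area), no decay."""
    spec = ModelSpec(n_chemicals=1, mech=_static_mech(),
                     chem=chem_mod.ChemistryParams(
                         production_rates=[1.0], decay_rates=[0.0],
                         permeability=[1.0], dt=kw.get("dt", 0.1)))
    spec.components["cell_chemistry"] = "source_decay"
    return spec


def model_coupling_receiver(**kw) -> ModelSpec:
    """No production; receives chemical 0 through the coupling only."""
    spec = ModelSpec(n_chemicals=1, mech=_static_mech(),
                     chem=chem_mod.ChemistryParams(
                         production_rates=[0.0], decay_rates=[0.0],
                         permeability=[1.0], dt=kw.get("dt", 0.1)))
    return spec


def model_leaf(**kw) -> ModelSpec:
    """Static tissue producing chemical 0 (constant rate, first-order decay);
    production latches off once chemical 1 reaches its threshold."""
    spec = ModelSpec(n_chemicals=2, mech=_static_mech(),
                     chem=chem_mod.ChemistryParams(
                         production_rates=[1.0, 0.0], decay_rates=[0.1, 0.1],
                         permeability=[1.0, 1.0], dt=kw.get("dt", 0.1)))
    spec.components["cell_chemistry"] = "leaf"
    spec.component_params.update({"stop_chemical": 1,
                                  "stop_threshold": kw.get("stop_threshold", 2.0)})
    return spec


def model_root(**kw) -> ModelSpec:
    """Grows (target-area increase) once chemical 0 reaches its threshold and
    produces chemical 1 while growing; no chemical-0 production."""
    spec = ModelSpec(n_chemicals=2, mech=mech_mod.MechParams(
                         temperature=0.0, step_amplitude=0.05,
                         energy_threshold=1e-3, max_mc_steps=20),
                     chem=chem_mod.ChemistryParams(
                         production_rates=[0.0, kw.get("production_rate", 2.0)],
                         decay_rates=[0.1, 0.1],
                         permeability=[1.0, 1.0], dt=kw.get("dt", 0.1)),
                     housekeep=chem_mod.HousekeepParams(
                         growth_rate=kw.get("growth_rate", 0.05),
                         growth_threshold=kw.get("growth_threshold", 1.0)))
    spec.components["cell_chemistry"] = "root"
    spec.components["cell_housekeep"] = "geometric_growth"
    spec.component_params["growth_trigger_chemical"] = 0
    return spec


def model_geometric(**kw) -> ModelSpec:
    """Pure growth and division, no chemistry."""
    spec = ModelSpec(n_chemicals=0, mech=mech_mod.MechParams(
                         temperature=0.0, step_amplitude=0.1,
                         energy_threshold=1e-2, max_mc_steps=50),
                     chem=chem_mod.ChemistryParams(
                         production_rates=np.zeros(1), decay_rates=np.zeros(1),
                         permeability=np.zeros(1), dt=kw.get("dt", 0.1)),
                     housekeep=chem_mod.HousekeepParams(
                         growth_rate=kw.get("growth_rate", 0.1),
                         growth_threshold=0.0))
    spec.components["cell_chemistry"] = "none"
    spec.components["cell_housekeep"] = "geometric_growth"
    spec.components["cell_split"] = "area_threshold"
    spec.division_factor = kw.get("division_factor", 2.0)
    spec.target_node_distance = kw.get("target_node_distance", 2.0)
    return spec


def builtin_models() -> dict:
    """Registry of demo model-spec factories."""
    return {
        "coupling_producer": model_coupling_producer,
        "coupling_receiver": model_coupling_receiver,
        "leaf": model_leaf,
        "root": model_root,
        "geometric": model_geometric,
    }


def make_demo_sim(name: str, n_rows=5, n_cols=5, cell_size=1.0,
                  seed: int = 0, static_geometry=None, **kw) -> SimState:
    """Grid tissue + demo model, ready to step.

    ``static_geometry`` fixes every node (the leaf and the coupling demo
    tissues are geometrically static); defaults to True for all demo models
    except ``geometric`` and ``root``.
    """
    spec = builtin_models()[name](**kw)
    spec.seed = seed
    mesh = generate_grid_tissue(n_rows, n_cols, cell_size, spec.n_chemicals)
    if static_geometry is None:
        static_geometry = name not in ("geometric", "root")
    if static_geometry:
        for node in mesh.nodes.values():
            node.fixed = True
    return build_sim((mesh, spec))
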
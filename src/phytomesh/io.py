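"""Tissue-file XML, coupling-spec CSV, time-series CSV, and sweeps.

The tissue file is a single versioned XML document holding the model
parameters (including component selections), all nodes, cells, and walls
with their attributes, plus an extensions block of free key/value pairs
(unknown parameters survive a read/write round trip there). Element order
and float formatting (17 significant digits) are canonical, so writing the
same state twice yields byte-identical text.
"""

from __future__ import annotations

import csv
import io as _io
import json
import os
import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd

from . import engine as engine_mod
from .chemistry import ChemistryParams, HousekeepParams
from .coupling import CouplingLink, CouplingSpec
from .engine import ModelSpec, SimState
from .mechanics import MechParams
from .mesh import TissueMesh, validate_mesh

SCHEMA_VERSION = "1"


class TissueFileError(ValueError):
    """Schema violation or unparseable tissue file."""


class MeshValidationError(ValueError):
    def __init__(self, violations):
        super().__init__("invalid mesh:\n" + "\n".join(violations))
        self.violations = violations


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _fmt_vec(v) -> str:
    return " ".join(_fmt(x) for x in np.atleast_1d(np.asarray(v, dtype=float)))


def _parse_vec(s: str) -> np.ndarray:
    return np.array([float(x) for x in s.split()]) if s.strip() else np.zeros(0)


# ---------------------------------------------------------------------------
# ModelSpec <-> flat parameter table

_MECH_FIELDS = ("hamiltonian", "lambda_area", "lambda_length",
                "target_edge_length", "turgor_pressure", "elastic_modulus",
                "wall_thickness", "temperature", "step_amplitude",
                "energy_threshold", "max_mc_steps", "termination",
                "window_size", "window_tol")
_CHEM_SCALARS = ("dt", "solver_rel_tol", "solver_abs_tol")
_CHEM_VECTORS = ("production_rates", "decay_rates", "permeability")
_HK_FIELDS = ("growth_rate", "growth_threshold", "yield_ratio",
              "yield_increment", "maxwell_tau")


def spec_to_params(spec: ModelSpec) -> dict:
    p = {
        "n_chemicals": str(spec.n_chemicals),
        "seed": str(spec.seed),
        "division_factor": _fmt(spec.division_factor),
        "division_axis": ("none" if spec.division_axis is None
                          else _fmt_vec(spec.division_axis)),
        "target_node_distance": ("none" if spec.target_node_distance is None
                                 else _fmt(spec.target_node_distance)),
    }
    for name in _MECH_FIELDS:
        v = getattr(spec.mech, name)
        p[f"mech.{name}"] = v if isinstance(v, str) else (
            str(v) if isinstance(v, int) else _fmt(v))
    for name in _CHEM_SCALARS:
        p[f"chem.{name}"] = _fmt(getattr(spec.chem, name))
    for name in _CHEM_VECTORS:
        p[f"chem.{name}"] = _fmt_vec(getattr(spec.chem, name))
    p["chem.boundary_permeability"] = (
        "none" if spec.chem.boundary_permeability is None
        else _fmt_vec(spec.chem.boundary_permeability))
    p["chem.production_by_type"] = json.dumps(
        {str(k): [float(x) for x in np.atleast_1d(v)]
         for k, v in sorted(spec.chem.production_by_type.items())})
    for name in _HK_FIELDS:
        p[f"housekeep.{name}"] = _fmt(getattr(spec.housekeep, name))
    p["component_params"] = json.dumps(spec.component_params, sort_keys=True)
    p["meta_definitions"] = json.dumps(
        {f"{t}:{n}": d for (t, n), d in sorted(spec.meta_definitions.items())},
        sort_keys=True)
    return p


def spec_from_params(params: dict, components: dict) -> ModelSpec:
    known = {}
    extensions = {}
    spec = ModelSpec()
    for key, raw in params.items():
        known[key] = raw
    try:
        spec.n_chemicals = int(known.pop("n_chemicals", "1"))
        spec.seed = int(known.pop("seed", "0"))
        spec.division_factor = float(known.pop("division_factor", "2"))
        da = known.pop("division_axis", "none")
        spec.division_axis = None if da == "none" else tuple(_parse_vec(da))
        tnd = known.pop("target_node_distance", "none")
        spec.target_node_distance = None if tnd == "none" else float(tnd)
        mech_kwargs = {}
        for name in _MECH_FIELDS:
            raw = known.pop(f"mech.{name}", None)
            if raw is None:
                continue
            if name in ("hamiltonian", "termination"):
                mech_kwargs[name] = raw
            elif name in ("max_mc_steps", "window_size"):
                mech_kwargs[name] = int(raw)
            else:
                mech_kwargs[name] = float(raw)
        spec.mech = MechParams(**mech_kwargs)
        chem_kwargs = {}
        for name in _CHEM_SCALARS:
            raw = known.pop(f"chem.{name}", None)
            if raw is not None:
                chem_kwargs[name] = float(raw)
        for name in _CHEM_VECTORS:
            raw = known.pop(f"chem.{name}", None)
            if raw is not None:
                chem_kwargs[name] = _parse_vec(raw)
        bp = known.pop("chem.boundary_permeability", "none")
        chem_kwargs["boundary_permeability"] = (None if bp == "none"
                                                else _parse_vec(bp))
        pbt = json.loads(known.pop("chem.production_by_type", "{}"))
        chem_kwargs["production_by_type"] = {int(k): np.asarray(v, dtype=float)
                                             for k, v in pbt.items()}
        spec.chem = ChemistryParams(**chem_kwargs)
        hk_kwargs = {name: float(known.pop(f"housekeep.{name}"))
                     for name in _HK_FIELDS if f"housekeep.{name}" in known}
        spec.housekeep = HousekeepParams(**hk_kwargs)
        spec.component_params = json.loads(known.pop("component_params", "{}"))
        md = json.loads(known.pop("meta_definitions", "{}"))
        spec.meta_definitions = {}
        for key, d in md.items():
            ctype, name = key.split(":", 1)
            spec.meta_definitions[(ctype, name)] = d
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise TissueFileError(f"bad parameter block: {exc}") from exc
    extensions.update(known)  # anything unrecognized is preserved
    spec.extensions = extensions
    spec.components = dict(engine_mod.DEFAULT_COMPONENTS)
    for ctype, name in components.items():
        spec.components[ctype] = name
    spec.mech.hamiltonian = spec.components.get("hamiltonian",
                                                spec.mech.hamiltonian)
    return spec


# ---------------------------------------------------------------------------
# tissue XML


def write_tissue_xml(mesh: TissueMesh, spec: ModelSpec,
                     extra_extensions: dict | None = None) -> str:
    """Serialize a tissue state canonically (stable, byte-identical)."""
    root = ET.Element("tissue", schema_version=SCHEMA_VERSION)

    params = ET.SubElement(root, "parameters")
    for key, value in sorted(spec_to_params(spec).items()):
        ET.SubElement(params, "param", name=key, value=value)
    for ctype in sorted(spec.components):
        name = spec.components[ctype]
        if isinstance(name, dict):
            name = "meta:" + json.dumps(name, sort_keys=True)
        ET.SubElement(params, "component", type=ctype, name=name)

    nodes = ET.SubElement(root, "nodes")
    for nid in sorted(mesh.nodes):
        n = mesh.nodes[nid]
        ET.SubElement(nodes, "node", id=str(nid), x=_fmt(n.x), y=_fmt(n.y),
                      fixed=str(int(n.fixed)), boundary=str(int(n.at_boundary)))

    cells = ET.SubElement(root, "cells")
    for cid in sorted(mesh.cells):
        c = mesh.cells[cid]
        el = ET.SubElement(cells, "cell", id=str(cid),
                           nodes=" ".join(str(i) for i in c.node_ids),
                           type=str(c.cell_type),
                           target_area=_fmt(c.target_area),
                           base_area=_fmt(c.base_area),
                           alive=str(int(c.alive)),
                           chem=_fmt_vec(c.chem_amounts))
        if c.flags:
            el.set("flags", json.dumps(c.flags, sort_keys=True))

    walls = ET.SubElement(root, "walls")
    for wid in sorted(mesh.walls):
        w = mesh.walls[wid]
        ET.SubElement(walls, "wall", id=str(wid), cell_a=str(w.cell_a),
                      cell_b=str(w.cell_b),
                      nodes=" ".join(str(i) for i in w.node_path),
                      rest_length=_fmt(w.rest_length),
                      stiffness=_fmt(w.stiffness),
                      transporters_a=_fmt_vec(w.transporters_a),
                      transporters_b=_fmt_vec(w.transporters_b))

    ext = ET.SubElement(root, "extensions")
    merged = dict(spec.extensions)
    merged.update(extra_extensions or {})
    for key in sorted(merged):
        ET.SubElement(ext, "ext", key=key, value=str(merged[key]))

    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"


def read_tissue_xml(text: str) -> tuple[TissueMesh, ModelSpec]:
    """Parse and validate a tissue file; returns the mesh and model spec."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise TissueFileError(f"not well-formed XML: {exc}") from exc
    if root.tag != "tissue":
        raise TissueFileError(f"root element is <{root.tag}>, expected <tissue>")
    if root.get("schema_version") != SCHEMA_VERSION:
        raise TissueFileError(
            f"schema_version {root.get('schema_version')!r} unsupported "
            f"(expected {SCHEMA_VERSION!r})")

    params, components = {}, {}
    pblock = root.find("parameters")
    if pblock is not None:
        for el in pblock:
            if el.tag == "param":
                params[el.get("name")] = el.get("value")
            elif el.tag == "component":
                name = el.get("name")
                if name.startswith("meta:"):
                    name = json.loads(name[5:])
                components[el.get("type")] = name
    spec = spec_from_params(params, components)
    eblock = root.find("extensions")
    if eblock is not None:
        for el in eblock:
            spec.extensions[el.get("key")] = el.get("value")

    mesh = TissueMesh(spec.n_chemicals)
    try:
        for el in root.find("nodes") or []:
            mesh.add_node(float(el.get("x")), float(el.get("y")),
                          fixed=bool(int(el.get("fixed", "0"))),
                          at_boundary=bool(int(el.get("boundary", "0"))),
                          node_id=int(el.get("id")))
        for el in root.find("cells") or []:
            cell = mesh.add_cell(
                [int(i) for i in el.get("nodes").split()],
                target_area=float(el.get("target_area")),
                cell_type=int(el.get("type", "0")),
                chem_amounts=_parse_vec(el.get("chem", "")),
                cell_id=int(el.get("id")),
                base_area=float(el.get("base_area")))
            cell.alive = bool(int(el.get("alive", "1")))
            if el.get("flags"):
                cell.flags = json.loads(el.get("flags"))
        for el in root.find("walls") or []:
            if el.get("cell_b") is None:
                raise TissueFileError(
                    f"wall {el.get('id')}: missing cell_b attribute")
            mesh.add_wall(int(el.get("cell_a")), int(el.get("cell_b")),
                          [int(i) for i in el.get("nodes").split()],
                          rest_length=float(el.get("rest_length")),
                          stiffness=float(el.get("stiffness", "1")),
                          transporters_a=_parse_vec(el.get("transporters_a", "")),
                          transporters_b=_parse_vec(el.get("transporters_b", "")),
                          wall_id=int(el.get("id")))
    except (TypeError, ValueError) as exc:
        if isinstance(exc, TissueFileError):
            raise
        raise TissueFileError(f"bad mesh element: {exc}") from exc

    violations = validate_mesh(mesh)
    if violations:
        raise MeshValidationError(violations)
    return mesh, spec


# ---------------------------------------------------------------------------
# snapshots (state + clock + RNG for exact resume)


def write_snapshot(sim: SimState) -> str:
    extra = {
        "step_index": str(sim.step_index),
        "sim_time": _fmt(sim.sim_time),
        "rng_state": json.dumps(sim.rng.bit_generator.state, sort_keys=True),
    }
    return write_tissue_xml(sim.mesh, sim.spec, extra_extensions=extra)


def load_snapshot(text: str) -> SimState:
    mesh, spec = read_tissue_xml(text)
    ext = spec.extensions
    sim = SimState(mesh, spec)
    if "step_index" in ext:
        sim.step_index = int(ext.pop("step_index"))
    if "sim_time" in ext:
        sim.sim_time = float(ext.pop("sim_time"))
    if "rng_state" in ext:
        sim.rng.bit_generator.state = json.loads(ext.pop("rng_state"))
    return sim


# ---------------------------------------------------------------------------
# time-series CSV


class CsvRecorder:
    """Observer recording per-cell and per-step aggregate time series."""

    def __init__(self, n_chemicals: int):
        self.n_chemicals = n_chemicals
        self.cell_rows = []
        self.agg_rows = []

    def __call__(self, step, time, sim: SimState):
        n_cells = 0
        total_area = 0.0
        totals = np.zeros(self.n_chemicals)
        for cid in sorted(sim.mesh.cells):
            cell = sim.mesh.cells[cid]
            area = sim.mesh.cell_area(cid)
            n_cells += 1
            total_area += area
            totals += cell.chem_amounts[:self.n_chemicals]
            self.cell_rows.append(
                [step, _fmt(time), cid, cell.cell_type, _fmt(area),
                 _fmt(cell.target_area)]
                + [_fmt(q) for q in cell.chem_amounts[:self.n_chemicals]])
        self.agg_rows.append([step, _fmt(time), n_cells, _fmt(total_area)]
                             + [_fmt(q) for q in totals])

    def cell_header(self):
        return (["step", "time", "cell_id", "cell_type", "area", "target_area"]
                + [f"C_{i}" for i in range(self.n_chemicals)])

    def agg_header(self):
        return (["step", "time", "n_cells", "total_area"]
                + [f"total_C_{i}" for i in range(self.n_chemicals)])

    def to_text(self) -> tuple[str, str]:
        def render(header, rows):
            buf = _io.StringIO()
            writer = csv.writer(buf, lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)
            return buf.getvalue()
        return (render(self.cell_header(), self.cell_rows),
                render(self.agg_header(), self.agg_rows))

    def write(self, out_dir: str):
        os.makedirs(out_dir, exist_ok=True)
        cells_text, agg_text = self.to_text()
        with open(os.path.join(out_dir, "cells.csv"), "w") as fh:
            fh.write(cells_text)
        with open(os.path.join(out_dir, "aggregate.csv"), "w") as fh:
            fh.write(agg_text)


# ---------------------------------------------------------------------------
# coupling-spec CSV


def write_coupling_csv(spec: CouplingSpec) -> str:
    lines = [f"n_slices={spec.n_slices}", "cell_a,cell_b,chemical,conductance"]
    for link in spec.links:
        lines.append(f"{link.cell_a},{link.cell_b},{link.chemical},"
                     f"{_fmt(link.conductance)}")
    return "\n".join(lines) + "\n"


def read_coupling_csv(text: str) -> CouplingSpec:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("n_slices="):
        raise TissueFileError("coupling file must start with 'n_slices=<int>'")
    n_slices = int(lines[0].split("=", 1)[1])
    if lines[1].replace(" ", "") != "cell_a,cell_b,chemical,conductance":
        raise TissueFileError("bad coupling CSV header")
    links = []
    for ln in lines[2:]:
        a, b, chem, g = ln.split(",")
        links.append(CouplingLink(int(a), int(b), int(chem), float(g)))
    return CouplingSpec(links=links, n_slices=n_slices)


# ---------------------------------------------------------------------------
# parameter sweeps


class SweepSpec:
    """One-parameter range sweep or multi-parameter CSV template.

    Range mode varies one dotted parameter over a list of values; template
    mode takes a CSV whose columns are dotted parameter names and whose rows
    are combinations. Every combination runs once per replicate seed.
    """

    def __init__(self, mode="range", parameter=None, values=None,
                 template_csv=None, seeds=(0,), n_steps=10):
        if mode not in ("range", "template"):
            raise ValueError(f"unknown sweep mode {mode!r}")
        self.mode = mode
        self.parameter = parameter
        self.values = list(values or [])
        self.template_csv = template_csv
        self.seeds = list(seeds)
        self.n_steps = int(n_steps)

    def combinations(self):
        if self.mode == "range":
            if not self.parameter:
                raise ValueError("range sweep needs a parameter name")
            return [{self.parameter: v} for v in self.values]
        rows = list(csv.DictReader(_io.StringIO(self.template_csv)))
        return [{k: _maybe_number(v) for k, v in row.items()} for row in rows]


def _maybe_number(s):
    try:
        f = float(s)
        return int(f) if f.is_integer() and "." not in s and "e" not in s.lower() else f
    except (TypeError, ValueError):
        return s


def run_sweep(spec: SweepSpec, tissue_text: str) -> pd.DataFrame:
    """Run the sweep serially; one result row per combination per seed.

    Failed runs are recorded with status='error' and do not abort the sweep.
    """
    records = []
    for combo in spec.combinations():
        for seed in spec.seeds:
            row = {**{k: v for k, v in combo.items()}, "seed": seed}
            try:
                overrides = dict(combo)
                overrides["seed"] = seed
                sim = engine_mod.build_sim(tissue_text, overrides=overrides)
                engine_mod.run(sim, spec.n_steps)
                row["status"] = "ok"
                row["n_cells"] = len(sim.mesh.cells)
                row["total_area"] = sim.mesh.total_area()
                for i in range(sim.mesh.n_chemicals):
                    row[f"total_C_{i}"] = float(sum(
                        c.chem_amounts[i] for c in sim.mesh.cells.values()))
                if sim.last_convergence is not None:
                    row["mc_converged"] = bool(sim.last_convergence[1])
            except Exception as exc:
                row["status"] = "error"
                row["error"] = str(exc)
            records.append(row)
    return pd.DataFrame.from_records(records)
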
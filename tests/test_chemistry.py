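import math

import numpy as np
import pytest

from phytomesh.chemistry import (
    ChemistryParams,
    ConfigurationError,
    HousekeepParams,
    assembled_derivatives,
    boundary_transport_rates,
    housekeep_elastic_wall,
    housekeep_geometric,
    housekeep_maxwell,
    integrate_slice,
    reaction_rates,
    transport_rates,
)
from phytomesh.mesh import generate_grid_tissue

from conftest import single_cell_mesh


def transport_only(n_chem=1, permeability=1.0):
    return ChemistryParams(production_rates=np.zeros(n_chem),
                           decay_rates=np.zeros(n_chem),
                           permeability=np.full(n_chem, permeability))


def total_amount(mesh, chem=0):
    return sum(float(c.chem_amounts[chem]) for c in mesh.cells.values())


class TestReactionRates:
    def test_pure_production_scales_with_area(self):
        mesh = single_cell_mesh([(0, 0), (2, 0), (2, 1), (0, 1)])  # area 2
        p = ChemistryParams(production_rates=[1.0], decay_rates=[0.0],
                            permeability=[0.0])
        rates = reaction_rates(mesh.cells[0], mesh, p)
        assert rates == pytest.approx([2.0])

    def test_first_order_decay(self, unit_square):
        unit_square.cells[0].chem_amounts[:] = [4.0]
        p = ChemistryParams(production_rates=[0.0], decay_rates=[0.5],
                            permeability=[0.0])
        assert reaction_rates(unit_square.cells[0], unit_square, p) == \
            pytest.approx([-2.0])

    def test_steady_state_reached(self):
        mesh = single_cell_mesh([(0, 0), (2, 0), (2, 1), (0, 1)])
        p = ChemistryParams(production_rates=[1.0], decay_rates=[1.0],
                            permeability=[0.0])
        integrate_slice(mesh, p, duration=20.0)
        # Q* = s*a/k = 2
        assert float(mesh.cells[0].chem_amounts[0]) == pytest.approx(2.0,
                                                                     abs=1e-6)


class TestTransportRates:
    def test_equal_concentrations_no_flux(self):
        mesh = generate_grid_tissue(2, 2, 1.0, 1)
        for c in mesh.cells.values():
            c.chem_amounts[:] = [3.0]
        rates = transport_rates(mesh, transport_only())
        assert all(abs(float(r[0])) < 1e-14 for r in rates.values())

    def test_two_cell_initial_flux(self):
        mesh = generate_grid_tissue(1, 2, 1.0, 1)
        ids = sorted(mesh.cells)
        mesh.cells[ids[0]].chem_amounts[:] = [1.0]
        rates = transport_rates(mesh, transport_only())
        assert float(rates[ids[0]][0]) == pytest.approx(-1.0)
        assert float(rates[ids[1]][0]) == pytest.approx(1.0)

    def test_two_cell_relaxation_closed_form(self):
        mesh = generate_grid_tissue(1, 2, 1.0, 1)
        ids = sorted(mesh.cells)
        mesh.cells[ids[0]].chem_amounts[:] = [1.0]
        p = transport_only()
        rate = 1.0 * 1.0 * (1.0 + 1.0)  # P*l*(1/a1+1/a2)
        t_accum = 0.0
        for dt in (0.5, 0.5, 1.0, 1.0, 2.0):
            integrate_slice(mesh, p, duration=dt)
            t_accum += dt
            c1 = float(mesh.cells[ids[0]].chem_amounts[0])
            exact = 0.5 + 0.5 * math.exp(-rate * t_accum)
            assert abs(c1 - exact) < 1e-6

    def test_symmetric_pair_equilibrates_to_equal_concentrations(self):
        mesh = generate_grid_tissue(1, 2, 1.0, 1)
        ids = sorted(mesh.cells)
        mesh.cells[ids[0]].chem_amounts[:] = [2.0]
        integrate_slice(mesh, transport_only(), duration=30.0)
        c0 = mesh.concentration(ids[0], 0)
        c1 = mesh.concentration(ids[1], 0)
        assert c0 == pytest.approx(c1, abs=1e-8)


class TestBoundaryTransport:
    def test_zero_flux_at_equal_concentration(self, unit_square):
        unit_square.cells[0].chem_amounts[:] = [1.0]
        bw = next(w.id for w in unit_square.walls.values() if w.is_boundary)
        rates = boundary_transport_rates(unit_square, {bw: [1.0]},
                                         transport_only())
        assert float(rates[0][0]) == pytest.approx(0.0, abs=1e-14)

    def test_influx_from_external_bath(self, unit_square):
        bw = next(w.id for w in unit_square.walls.values() if w.is_boundary)
        rates = boundary_transport_rates(unit_square, {bw: [1.0]},
                                         transport_only())
        assert float(rates[0][0]) == pytest.approx(1.0)

    def test_dirichlet_relaxation(self, unit_square):
        bw = next(w.id for w in unit_square.walls.values() if w.is_boundary)
        integrate_slice(unit_square, transport_only(),
                        boundary_conditions={bw: [1.0]}, duration=20.0)
        assert unit_square.concentration(0, 0) == pytest.approx(1.0, abs=1e-4)

    def test_condition_on_internal_wall_rejected(self):
        mesh = generate_grid_tissue(1, 2, 1.0, 1)
        internal = next(w.id for w in mesh.walls.values() if not w.is_boundary)
        with pytest.raises(ConfigurationError):
            boundary_transport_rates(mesh, {internal: [1.0]}, transport_only())


class TestIntegrateSlice:
    def test_zero_rates_leave_amounts(self, grid5):
        for c in grid5.cells.values():
            c.chem_amounts[:] = [2.0]
        integrate_slice(grid5, ChemistryParams(production_rates=[0.0],
                                               decay_rates=[0.0],
                                               permeability=[0.0]),
                        duration=1.0)
        assert all(float(c.chem_amounts[0]) == 2.0 for c in grid5.cells.values())

    def test_closed_system_conservation(self, rng):
        mesh = generate_grid_tissue(5, 5, 1.0, 1)
        for c in mesh.cells.values():
            c.chem_amounts[:] = [rng.uniform(0, 5)]
        before = total_amount(mesh)
        for _ in range(100):
            integrate_slice(mesh, transport_only(), duration=0.1)
        assert abs(total_amount(mesh) - before) < 1e-8

    def test_matches_fixed_step_rk4_oracle(self, rng):
        mesh = generate_grid_tissue(3, 3, 1.0, 1)
        for c in mesh.cells.values():
            c.chem_amounts[:] = [rng.uniform(0, 3)]
        p = ChemistryParams(production_rates=[0.3], decay_rates=[0.2],
                            permeability=[1.0])
        ref = mesh.copy()
        duration = 1.0
        integrate_slice(mesh, p, duration=duration)

        # independent oracle: classical RK4 at dt/1000 on the same system
        from phytomesh.chemistry import _OdeSystem
        sys = _OdeSystem(ref, p)
        y = sys.initial_amounts()
        h = duration / 1000
        for _ in range(1000):
            k1 = sys.derivatives(y)
            k2 = sys.derivatives(y + h / 2 * k1)
            k3 = sys.derivatives(y + h / 2 * k2)
            k4 = sys.derivatives(y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        ours = np.concatenate([mesh.cells[c].chem_amounts
                               for c in sorted(mesh.cells)])
        assert np.max(np.abs(ours - y)) < 1e-6

    def test_global_mass_balance_audit(self, rng):
        """d(total)/dt equals production - decay - boundary efflux."""
        mesh = generate_grid_tissue(3, 3, 1.0, 1)
        for c in mesh.cells.values():
            c.chem_amounts[:] = [rng.uniform(0.5, 2)]
        p = ChemistryParams(production_rates=[0.7], decay_rates=[0.3],
                            permeability=[1.0])
        bw = next(w.id for w in mesh.walls.values() if w.is_boundary)
        bc = {bw: [2.0]}
        dq = assembled_derivatives(mesh, p, boundary_conditions=bc)
        total_rate = sum(float(v[0]) for v in dq.values())
        production = sum(0.7 * mesh.cell_area(c) for c in mesh.cells)
        decay = sum(0.3 * float(c.chem_amounts[0]) for c in mesh.cells.values())
        wall = mesh.walls[bw]
        influx = 1.0 * mesh.wall_length(bw) * (
            2.0 - mesh.concentration(wall.cell_a, 0))
        assert total_rate == pytest.approx(production - decay + influx,
                                           abs=1e-10)

    def test_permeability_monotonicity(self):
        """Higher permeability gives a more equal producer/receiver split."""
        diffs = []
        for perm in (0.0, 0.01, 0.1, 1.0):
            mesh = generate_grid_tissue(1, 2, 1.0, 1)
            ids = sorted(mesh.cells)
            p = ChemistryParams(production_rates=[0.0], decay_rates=[0.0],
                                permeability=[perm],
                                production_by_type={1: np.array([1.0])})
            mesh.cells[ids[0]].cell_type = 1  # the producer
            for _ in range(20):
                integrate_slice(mesh, p, duration=0.1)
            diffs.append(float(mesh.cells[ids[0]].chem_amounts[0])
                         - float(mesh.cells[ids[1]].chem_amounts[0]))
        assert all(b <= a + 1e-12 for a, b in zip(diffs, diffs[1:]))


class TestHousekeep:
    def test_geometric_growth_below_threshold_noop(self, unit_square):
        hk = HousekeepParams(growth_rate=0.1, growth_threshold=1.0)
        unit_square.cells[0].chem_amounts[:] = [0.5]
        housekeep_geometric(unit_square, hk)
        assert unit_square.cells[0].target_area == pytest.approx(1.0)

    def test_geometric_growth_compounds_exactly(self, unit_square):
        hk = HousekeepParams(growth_rate=0.1, growth_threshold=1.0)
        unit_square.cells[0].chem_amounts[:] = [5.0]
        for _ in range(4):
            housekeep_geometric(unit_square, hk)
        assert unit_square.cells[0].target_area == pytest.approx(1.1 ** 4,
                                                                 rel=1e-15)

    def test_elastic_yield_threshold(self, unit_square):
        hk = HousekeepParams(yield_ratio=1.5, yield_increment=0.1)
        w = unit_square.walls[0]
        w.rest_length = 1.0 / 1.4  # l/l0 = 1.4 < 1.5
        housekeep_elastic_wall(unit_square, hk)
        assert w.rest_length == pytest.approx(1.0 / 1.4)
        w.rest_length = 1.0 / 1.6  # l/l0 = 1.6 > 1.5
        before = w.rest_length
        housekeep_elastic_wall(unit_square, hk)
        assert w.rest_length == pytest.approx(before * 1.1)

    def test_elastic_yield_converges_to_ratio_bound(self, unit_square):
        hk = HousekeepParams(yield_ratio=1.5, yield_increment=0.1)
        w = unit_square.walls[0]
        w.rest_length = 0.2  # heavily stretched (l = 1)
        lengths = []
        for _ in range(50):
            housekeep_elastic_wall(unit_square, hk)
            lengths.append(w.rest_length)
        assert all(b >= a for a, b in zip(lengths, lengths[1:]))  # irreversible
        assert 1.0 / w.rest_length <= hk.yield_ratio

    def test_maxwell_relaxation_closed_form(self, unit_square):
        hk = HousekeepParams(maxwell_tau=3.0)
        w = unit_square.walls[0]
        w.rest_length = 0.4
        housekeep_maxwell(unit_square, hk, dt=0.7)
        expected = 1.0 + (0.4 - 1.0) * math.exp(-0.7 / 3.0)
        assert w.rest_length == pytest.approx(expected, abs=1e-12)

    def test_maxwell_identity_and_elastic_limit(self, unit_square):
        hk = HousekeepParams(maxwell_tau=1e12)
        w = unit_square.walls[0]
        w.rest_length = 0.4
        housekeep_maxwell(unit_square, hk, dt=0.1)
        assert w.rest_length == pytest.approx(0.4, abs=1e-9)
        hk2 = HousekeepParams(maxwell_tau=1.0)
        w.rest_length = unit_square.wall_length(w.id)  # l == l0
        housekeep_maxwell(unit_square, hk2, dt=5.0)
        assert w.rest_length == pytest.approx(unit_square.wall_length(w.id))
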
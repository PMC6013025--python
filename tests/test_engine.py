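"""Growth, division, shoving and the simulation loop."""

import numpy as np
import pandas as pd
import pytest

from duofilm.cells import CellPopulation, mass_from_radius
from duofilm.engine import (SimulationConfig, divide_cells, grow_cells,
                            initial_state, run_simulation, simulation_step)
from duofilm.mechanics import max_overlap, relax_overlaps_population
from duofilm.model import ConfigurationError
from duofilm.solver import DomainGeometry

from conftest import population

TINY_GEOM = DomainGeometry(width=40.0, height=60.0, grid_spacing=2.0,
                           boundary_layer=10.0)


def tiny_config(**overrides):
    defaults = dict(medium="exploitation_competition", n_R=6, n_S=6,
                    duration_h=4.0, dt_h=0.05, snapshot_every_h=1.0,
                    geometry=TINY_GEOM, seed=42)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def _state_with_uniform_fields(cells, N=0.05, A=0.0, **overrides):
    cfg = tiny_config(antibiotic_bulk=A, **overrides)
    state = initial_state(cfg)
    state.cells = cells
    for f in state.fields:
        f.values[:] = {"N": N, "A": A}.get(f.spec.name, f.spec.bulk_value)
    return state


class TestGrow:
    def test_no_substrate_no_growth(self):
        pop = population([("R", 5.0, 1.0, 300.0)])
        state = _state_with_uniform_fields(pop, N=0.0)
        grow_cells(state, 0.05)
        assert pop.mass[0] == 300.0

    def test_exponential_update(self):
        pop = population([("R", 5.0, 1.0, 300.0)])
        state = _state_with_uniform_fields(pop, N=0.05)
        grow_cells(state, 0.02)
        assert pop.mass[0] / 300.0 == pytest.approx(
            np.exp(0.99930049 * 0.02), rel=1e-6)

    def test_antibiotic_slows_susceptible_by_inhibition_factor(self):
        rates = {}
        for A in (0.0, 0.2):
            pop = population([("S", 5.0, 1.0, 300.0)])
            state = _state_with_uniform_fields(pop, N=0.05, A=A)
            grow_cells(state, 0.1)
            rates[A] = np.log(pop.mass[0] / 300.0) / 0.1
        assert rates[0.2] / rates[0.0] == pytest.approx(1.0 / 3.0, rel=1e-9)

    def test_invalid_dt(self):
        state = _state_with_uniform_fields(population([("R", 5, 1, 300)]))
        with pytest.raises(ConfigurationError):
            grow_cells(state, 0.0)


class TestDivide:
    def test_symmetric_split(self):
        pop = population([("R", 5.0, 1.0, 700.0)])
        state = _state_with_uniform_fields(pop)
        state.rng = np.random.default_rng(0)

        class HalfRng:
            def uniform(self, lo, hi, size=None):
                if (lo, hi) == (0.45, 0.55):
                    return np.full(size, 0.5)
                return np.zeros(size)

        state.rng = HalfRng()
        divide_cells(state)
        assert len(state.cells) == 2
        assert sorted(state.cells.mass) == [350.0, 350.0]

    def test_mass_conserved_and_ids_fresh(self, rng):
        masses = rng.uniform(100, 900, size=20)
        pop = population([("S", 1 + i * 1.5, 1.0, m)
                          for i, m in enumerate(masses)])
        state = _state_with_uniform_fields(pop)
        state.next_id = 20
        total_before = state.cells.mass.sum()
        divide_cells(state)
        assert state.cells.mass.sum() == pytest.approx(total_before)
        assert len(np.unique(state.cells.ids)) == len(state.cells)
        m_div = state.config.division_mass
        assert (state.cells.mass < m_div).all()

    def test_below_threshold_untouched(self):
        pop = population([("R", 5.0, 1.0, 300.0)])
        state = _state_with_uniform_fields(pop)
        divide_cells(state)
        assert len(state.cells) == 1 and state.cells.mass[0] == 300.0


class TestShoving:
    def test_touching_pair_unchanged(self):
        m = mass_from_radius(1.0)
        pop = population([("R", 10.0, 1.0, m), ("S", 12.0, 1.0, m)])
        x0 = pop.x.copy()
        relax_overlaps_population(pop, 40.0)
        assert np.allclose(pop.x, x0)

    def test_superposed_pair_pushed_to_touching(self):
        m = mass_from_radius(1.0)
        pop = population([("R", 10.0, 2.0, m), ("S", 10.0, 2.0, m)])
        relax_overlaps_population(pop, 40.0)
        d = np.hypot(pop.x[1] - pop.x[0], pop.y[1] - pop.y[0])
        assert d == pytest.approx(2.0, abs=0.05)
        mid = (pop.x[0] + pop.x[1]) / 2
        assert mid == pytest.approx(10.0, abs=1e-9)

    def test_isolated_cell_unchanged(self):
        pop = population([("R", 10.0, 5.0, 300.0)])
        relax_overlaps_population(pop, 40.0)
        assert pop.x[0] == 10.0 and pop.y[0] >= pop.radius[0]

    def test_crowd_settles_below_tolerance(self, rng):
        m = mass_from_radius(1.0)
        pop = population([("R", float(x), 1.0 + float(dy), m)
                          for x, dy in zip(rng.uniform(0, 20, size=40),
                                           rng.uniform(0, 0.01, size=40))])
        relax_overlaps_population(pop, 40.0)
        assert max_overlap(pop, 40.0) < 0.0101
        assert (pop.y >= pop.radius - 1e-9).all()


class TestSimulationLoop:
    def test_zero_dt_refreshes_fields_only(self):
        cfg = tiny_config()
        state = initial_state(cfg)
        cells_before = state.cells.copy()
        simulation_step(state, 0.0)
        assert state.time == 0.0
        assert np.array_equal(state.cells.mass, cells_before.mass)
        assert np.array_equal(state.cells.x, cells_before.x)

    def test_empty_population_fields_go_to_bulk(self):
        cfg = tiny_config(n_R=1, n_S=0, antibiotic_bulk=0.05)
        state = initial_state(cfg)
        state.cells = CellPopulation()
        simulation_step(state, 0.0)
        for f in state.fields:
            assert np.allclose(f.values, f.bulk)

    def test_duration_zero_single_snapshot(self):
        res = run_simulation(tiny_config(duration_h=0.0))
        assert len(res.snapshots) == 1 and res.snapshots[0][0] == 0.0

    def test_determinism_same_seed(self):
        r1 = run_simulation(tiny_config(duration_h=2.0))
        r2 = run_simulation(tiny_config(duration_h=2.0))
        pd.testing.assert_frame_equal(r1.metrics, r2.metrics)
        assert np.array_equal(r1.final_state.cells.x, r2.final_state.cells.x)
        assert np.array_equal(r1.final_state.cells.mass,
                              r2.final_state.cells.mass)

    def test_masses_never_shrink(self):
        res = run_simulation(tiny_config(duration_h=3.0,
                                         antibiotic_bulk=0.2))
        for (t0, a), (t1, b) in zip(res.snapshots, res.snapshots[1:]):
            assert b.mass.sum() >= a.mass.sum() - 1e-9
            common, ia, ib = np.intersect1d(a.ids, b.ids,
                                            return_indices=True)
            assert (b.mass[ib] >= a.mass[ia] - 1e-9).all()

    def test_confinement_after_steps(self):
        res = run_simulation(tiny_config(duration_h=3.0))
        pop = res.final_state.cells
        assert (pop.y >= pop.radius - 1e-9).all()
        assert (pop.x >= 0).all() and (pop.x < TINY_GEOM.width).all()
        assert max_overlap(pop, TINY_GEOM.width) < 0.0101

    def test_cell_count_non_decreasing(self):
        res = run_simulation(tiny_config(duration_h=3.0))
        counts = res.metrics["count_R"] + res.metrics["count_S"]
        assert counts.is_monotonic_increasing

    def test_late_antibiotic_equivalent_to_none(self):
        a = run_simulation(tiny_config(duration_h=2.0, antibiotic_bulk=0.2,
                                       antibiotic_start_time=2.0))
        b = run_simulation(tiny_config(duration_h=2.0, antibiotic_bulk=0.0))
        pd.testing.assert_frame_equal(a.metrics, b.metrics)

    def test_antibiotic_start_time_matters(self):
        a = run_simulation(tiny_config(duration_h=2.0, antibiotic_bulk=0.2,
                                       n_R=0, n_S=8))
        b = run_simulation(tiny_config(duration_h=2.0, antibiotic_bulk=0.2,
                                       antibiotic_start_time=1.0,
                                       n_R=0, n_S=8))
        assert b.metrics["biomass_S_fg"].iloc[-1] \
            > a.metrics["biomass_S_fg"].iloc[-1]

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            tiny_config(dt_h=0.0)
        with pytest.raises(ConfigurationError):
            tiny_config(n_R=0, n_S=0)


class TestClosedSystemMassBalance:
    def test_nutrient_plus_biomass_conserved(self):
        """Sealed microcosm: yield-weighted biomass gain equals nutrient
        drawn from the finite pool (0.5% over 10 h)."""
        cfg = tiny_config(duration_h=10.0, closed_system=True,
                          initial_nutrient=5.0, n_R=4, n_S=4)
        res = run_simulation(cfg)
        geom = cfg.geometry
        volume = geom.width * geom.height
        m0 = res.snapshots[0][1].mass.sum()
        m1 = res.snapshots[-1][1].mass.sum()
        pool_cols = [c for c in res.metrics.columns if c.startswith("pool_N")]
        n_left = res.metrics[pool_cols[0]].iloc[-1] * volume
        n0 = 5.0 * volume
        consumed = (m1 - m0) / 0.5  # 1/Y_N
        assert consumed + n_left == pytest.approx(n0, rel=0.005)
        assert m1 > 2 * m0  # growth actually happened

    def test_growth_stops_when_pool_empty(self):
        cfg = tiny_config(duration_h=30.0, closed_system=True,
                          initial_nutrient=0.002, n_R=4, n_S=4)
        res = run_simulation(cfg)
        tail = res.metrics.iloc[-3:]["biomass_R_fg"]
        assert tail.iloc[-1] == pytest.approx(tail.iloc[0], rel=1e-6)
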
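"""Pseudo-steady-state reaction-diffusion solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duofilm.cells import CellPopulation
from duofilm.model import ParameterSet, StateError, build_medium
from duofilm.solver import (BiomassGrid, DomainGeometry,
                            biofilm_height, locate_front_and_clamp,
                            make_fields, rasterize_biomass,
                            solve_pseudo_steady_state,
                            steady_state_residual)

from conftest import population


class TestRasterize:
    def test_empty(self, small_geometry):
        grid = rasterize_biomass(CellPopulation(), small_geometry)
        assert not grid.X_R.any() and not grid.X_S.any()

    def test_single_cell_concentration(self, small_geometry):
        pop = population([("R", 1.0, 1.0, 500.0)])
        grid = rasterize_biomass(pop, small_geometry)
        # 500 fg in a 2x2x1 um^3 voxel -> 125 g/L
        assert grid.X_R[0, 0] == pytest.approx(125.0)
        assert grid.X_R.sum() == pytest.approx(125.0)

    def test_additivity(self, small_geometry):
        pop = population([("R", 1.0, 1.0, 500.0), ("R", 1.5, 0.5, 100.0),
                          ("S", 1.0, 1.0, 200.0)])
        grid = rasterize_biomass(pop, small_geometry)
        assert grid.X_R[0, 0] == pytest.approx(150.0)
        assert grid.X_S[0, 0] == pytest.approx(50.0)

    def test_outside_domain_rejected(self, small_geometry):
        pop = population([("R", 50.0, 1.0, 100.0)])  # x > width
        with pytest.raises(StateError):
            rasterize_biomass(pop, small_geometry)

    @given(st.lists(st.tuples(st.sampled_from("RS"),
                              st.floats(0, 39.99), st.floats(0, 59.99),
                              st.floats(1, 1000)), max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_mass_conservation(self, specs):
        geom = DomainGeometry(width=40.0, height=60.0, grid_spacing=2.0,
                              boundary_layer=10.0)
        pop = population(specs)
        grid = rasterize_biomass(pop, geom)
        vol = geom.voxel_volume
        assert grid.X_R.sum() * vol == pytest.approx(pop.total_mass("R"),
                                                     abs=1e-9)
        assert grid.X_S.sum() * vol == pytest.approx(pop.total_mass("S"),
                                                     abs=1e-9)


class TestClamping:
    def test_empty_biofilm_clamps_above_boundary_layer(self, small_geometry,
                                                       params):
        med = build_medium("exploitation_competition", params)
        grid = make_fields(med, small_geometry)[0]
        bio = rasterize_biomass(CellPopulation(), small_geometry)
        mask = locate_front_and_clamp(grid, bio)
        # boundary layer 10 um = 5 rows: rows >= 5 clamped
        assert mask[5:, :].all() and not mask[:5, :].any()

    def test_clamp_height_follows_front(self, params):
        geom = DomainGeometry(width=40.0, height=120.0, grid_spacing=2.0,
                              boundary_layer=40.0)
        med = build_medium("exploitation_competition", params)
        grid = make_fields(med, geom)[0]
        pop = population([("R", 10.0, 29.0, 100.0)])  # front at 30 um
        mask = locate_front_and_clamp(grid, rasterize_biomass(pop, geom))
        first_clamped = int(np.argmax(mask[:, 0]))
        assert first_clamped * geom.grid_spacing == 70.0  # 30 + 40

    def test_zero_bulk_solutes_clamped_to_zero(self, small_geometry, params):
        med = build_medium("interference_competition", params)
        fields = make_fields(med, small_geometry)
        toxin = next(f for f in fields if f.spec.name == "T_R")
        toxin.values[:] = 7.0
        bio = rasterize_biomass(CellPopulation(), small_geometry)
        locate_front_and_clamp(toxin, bio)
        assert (toxin.values[5:, :] == 0.0).all()


def _uniform_slab_case(h, K=50.0, X=100.0, slab_um=32.0, gap_rows=4):
    """Uniform biomass slab consuming a nearly-linear (C << K) nutrient."""
    params = ParameterSet(K_N=K, N_bulk=0.05)
    med = build_medium("exploitation_competition", params)
    height = slab_um + gap_rows * h + 6 * h
    geom = DomainGeometry(width=8 * h, height=height, grid_spacing=h,
                          boundary_layer=gap_rows * h)
    ny, nx = geom.ny, geom.nx
    n_slab = int(round(slab_um / h))
    X_R = np.zeros((ny, nx))
    X_R[:n_slab, :] = X
    bio = BiomassGrid(geometry=geom, X_R=X_R, X_S=np.zeros((ny, nx)))
    fields = make_fields(med, geom)
    solve_pseudo_steady_state(fields, bio, med, tol=1e-10)
    # analytic: C = B cosh(q y) in slab, linear in the diffusion gap,
    # Dirichlet bulk at the first clamped node centre
    D = med.solute("N").diffusivity
    k = X * params.mu_max / (params.Y_N * K)
    q = np.sqrt(k / D)
    L = slab_um
    y_clamp = (n_slab + gap_rows + 0.5) * h
    B = 0.05 / (np.cosh(q * L) + q * np.sinh(q * L) * (y_clamp - L))
    y = (np.arange(n_slab) + 0.5) * h
    analytic = B * np.cosh(q * y)
    numeric = fields[0].values[:n_slab, 0]
    return numeric, analytic, fields, bio, med


class TestSteadyState:
    def test_zero_biomass_gives_uniform_bulk(self, small_geometry, params):
        med = build_medium("crossfeeding", params)
        fields = make_fields(med, small_geometry)
        for f in fields:
            f.values[:] = 0.123  # stale start
        bio = rasterize_biomass(CellPopulation(), small_geometry)
        solve_pseudo_steady_state(fields, bio, med)
        for f in fields:
            assert np.allclose(f.values, f.spec.bulk_value)

    def test_slab_matches_cosh_profile(self):
        numeric, analytic, *_ = _uniform_slab_case(h=1.0)
        rel = np.abs(numeric - analytic) / analytic
        assert rel.max() < 0.01

    def test_grid_convergence_second_order(self):
        # stiffer sink so the O(h^2) discretisation error dominates the
        # (tiny) Monod-linearisation bias of the analytic reference
        errs = []
        for h in (2.0, 1.0, 0.5):
            numeric, analytic, *_ = _uniform_slab_case(h=h, K=500.0, X=5e4)
            errs.append(np.max(np.abs(numeric - analytic) / analytic))
        assert errs[0] / errs[1] > 3.0
        assert errs[1] / errs[2] > 3.0

    def test_flux_balance(self):
        """Diffusive influx through the clamped interface equals total
        consumption in the domain (discrete divergence theorem)."""
        numeric, analytic, fields, bio, med = _uniform_slab_case(h=1.0)
        geom = bio.geometry
        f = fields[0]
        h = geom.grid_spacing
        n_active = int(np.argmax(
            locate_front_and_clamp(f, bio)[:, 0]))
        D = f.spec.diffusivity
        influx = D * (f.bulk - f.values[n_active - 1, :]).sum() / h * h
        from duofilm.model import solute_source_terms
        src = solute_source_terms(med, bio.as_mapping(),
                                  {g.spec.name: g.values for g in fields})
        consumption = -np.asarray(src["N"]).sum() * h * h
        assert influx == pytest.approx(consumption, rel=1e-3)

    def test_residual_small_at_convergence(self):
        *_, fields, bio, med = _uniform_slab_case(h=2.0)
        res = steady_state_residual(fields, bio, med)
        assert res["N"] < 1e-6

    def test_maximum_principle(self, params, rng):
        """Consumed solutes stay below bulk; secreted toxins stay >= 0."""
        med = build_medium("interference_competition", params)
        geom = DomainGeometry(width=40.0, height=60.0, grid_spacing=2.0,
                              boundary_layer=10.0)
        X_R = np.zeros((geom.ny, geom.nx))
        X_S = np.zeros((geom.ny, geom.nx))
        X_R[:5] = rng.uniform(0, 200, size=(5, geom.nx))
        X_S[:5] = rng.uniform(0, 200, size=(5, geom.nx))
        bio = BiomassGrid(geometry=geom, X_R=X_R, X_S=X_S)
        fields = make_fields(med, geom)
        solve_pseudo_steady_state(fields, bio, med, tol=1e-8)
        by_name = {f.spec.name: f.values for f in fields}
        assert by_name["N"].max() <= 0.05 * (1 + 1e-9)
        assert by_name["N"].min() >= 0.0
        for t in ("T_R", "T_S"):
            assert by_name[t].min() >= 0.0
            assert by_name[t].max() > 0.0  # toxins actually produced

    def test_warm_start_independence(self, params):
        med = build_medium("exploitation_competition", params)
        geom = DomainGeometry(width=40.0, height=60.0, grid_spacing=2.0,
                              boundary_layer=10.0)
        X_R = np.zeros((geom.ny, geom.nx))
        X_R[:3] = 150.0
        bio = BiomassGrid(geometry=geom, X_R=X_R, X_S=np.zeros_like(X_R))
        tol = 1e-8
        cold = make_fields(med, geom)
        for f in cold:
            f.values[:] = 0.0
        warm = make_fields(med, geom)
        solve_pseudo_steady_state(cold, bio, med, tol=tol)
        solve_pseudo_steady_state(warm, bio, med, tol=tol)
        assert np.max(np.abs(cold[0].values - warm[0].values)) < 10 * tol * 0.05

    def test_lateral_periodicity(self, params):
        """Translating the biomass laterally translates the solution."""
        med = build_medium("exploitation_competition", params)
        geom = DomainGeometry(width=40.0, height=60.0, grid_spacing=2.0,
                              boundary_layer=10.0)
        rng = np.random.default_rng(7)
        X_R = np.zeros((geom.ny, geom.nx))
        X_R[:4] = rng.uniform(0, 200, size=(4, geom.nx))
        shift = 5
        for roll in (0, shift):
            bio = BiomassGrid(geometry=geom, X_R=np.roll(X_R, roll, axis=1),
                              X_S=np.zeros_like(X_R))
            fields = make_fields(med, geom)
            solve_pseudo_steady_state(fields, bio, med, tol=1e-10)
            if roll == 0:
                base = fields[0].values.copy()
        assert np.max(np.abs(np.roll(base, shift, axis=1)
                             - fields[0].values)) < 1e-6


def test_inner_solver_paths_agree(params, monkeypatch):
    """The SOR kernel and the sparse direct fallback give the same field."""
    import duofilm.solver as solver_mod
    med = build_medium("crossfeeding", params)
    geom = DomainGeometry(width=40.0, height=60.0, grid_spacing=2.0,
                          boundary_layer=10.0)
    rng = np.random.default_rng(3)
    X_R = np.zeros((geom.ny, geom.nx))
    X_S = np.zeros((geom.ny, geom.nx))
    X_R[:3] = rng.uniform(0, 150, size=(3, geom.nx))
    X_S[:3] = rng.uniform(0, 150, size=(3, geom.nx))
    bio = BiomassGrid(geometry=geom, X_R=X_R, X_S=X_S)
    results = {}
    for label, kernel in [("sor", solver_mod._sor_solve), ("direct", None)]:
        monkeypatch.setattr(solver_mod, "_sor_solve", kernel)
        fields = make_fields(med, geom)
        solve_pseudo_steady_state(fields, bio, med, tol=1e-9)
        results[label] = {f.spec.name: f.values.copy() for f in fields}
    for name in results["sor"]:
        assert np.allclose(results["sor"][name], results["direct"][name],
                           atol=1e-7, rtol=1e-5)


def test_biofilm_height(small_geometry):
    pop = population([("R", 1.0, 1.0, 100.0), ("S", 21.0, 9.0, 100.0)])
    bio = rasterize_biomass(pop, small_geometry)
    # columns: one topped at 2 um, one at 10 um, rest 0 -> mean = 12/20
    assert biofilm_height(bio) == pytest.approx((2.0 + 10.0) / 20.0)
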
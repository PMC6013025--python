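"""Simulation engine: growth, division and the main time loop.

One step advances the agent population by ``dt`` hours:

1. deposit cell biomass on the grid and relax every solute field to its
   pseudo steady state;
2. grow each cell exponentially at the specific growth rate evaluated at
   its voxel's solute concentrations (bacteriostatic antibiotic: growth
   slows, mass never shrinks);
3. split cells that reached the division mass into two daughters with a
   small random mass asymmetry;
4. shove overlapping cells apart.

Cells never die or detach; a starved cell simply stops growing until
substrate returns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .cells import (DEFAULT_DENSITY, DEFAULT_DIVISION_RADIUS, CellPopulation,
                    mass_from_radius, radius_from_mass)
from .mechanics import relax_overlaps_population
from .model import (ConfigurationError, MediumDefinition, ParameterSet,
                    SpeciesSpec, build_medium, reaction_rate_per_biomass,
                    species_pair)
from .solver import (BiomassGrid, DomainGeometry, SoluteGrid, biofilm_height,
                     make_fields, rasterize_biomass,
                     solve_pseudo_steady_state)

__all__ = ["SimulationConfig", "SimulationState", "SimulationResult",
           "initial_state", "grow_cells", "divide_cells", "relax_overlaps",
           "simulation_step", "run_simulation"]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulation run."""

    medium: str = "exploitation_competition"
    antibiotic_bulk: float = 0.0           # g/L
    antibiotic_start_time: float = 0.0     # h; bulk antibiotic is 0 before
    cost: float = 0.0                      # 1/h (or fraction of mu_max, see below)
    alpha: float = 0.0                     # g antibiotic / g biomass
    n_R: int = 120
    n_S: int = 120
    arrangement: str = "random"            # or "segregated"
    duration_h: float = 36.0
    dt_h: float = 0.02
    snapshot_every_h: float = 2.0
    seed: int = 0
    geometry: DomainGeometry = field(default_factory=DomainGeometry)
    params: ParameterSet = field(default_factory=ParameterSet)
    density_g_per_L: float = DEFAULT_DENSITY
    division_radius_um: float = DEFAULT_DIVISION_RADIUS
    solver_tol: float = 1e-6
    closed_system: bool = False            # sealed microcosm (test variant)
    initial_nutrient: float | None = None  # closed-system starting pool (g/L)

    def __post_init__(self) -> None:
        if self.dt_h <= 0:
            raise ConfigurationError("dt_h must be positive")
        if self.duration_h < 0:
            raise ConfigurationError("duration_h must be non-negative")
        if self.n_R + self.n_S < 1:
            raise ConfigurationError("inoculum must contain at least one cell")

    @property
    def division_mass(self) -> float:
        return float(mass_from_radius(self.division_radius_um,
                                      self.density_g_per_L))

    def build_medium(self) -> MediumDefinition:
        params = replace(self.params, A_bulk=self.antibiotic_bulk)
        return build_medium(self.medium, params, cost_c=self.cost,
                            alpha_detox=self.alpha)

    def build_species(self) -> dict[str, SpeciesSpec]:
        R, S = species_pair(self.params, cost_c=self.cost,
                            alpha_detox=self.alpha)
        return {"R": R, "S": S}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        geom = d.pop("domain", None) or d.pop("geometry", None)
        if isinstance(geom, dict):
            d["geometry"] = DomainGeometry(**geom)
        elif geom is not None:
            d["geometry"] = geom
        inoc = d.pop("inoculum", None)
        if isinstance(inoc, dict):
            d.setdefault("n_R", inoc.get("n_R", 120))
            d.setdefault("n_S", inoc.get("n_S", 120))
            d.setdefault("arrangement", inoc.get("arrangement", "random"))
        params = d.pop("params", None)
        if isinstance(params, dict):
            d["params"] = ParameterSet(**params)
        return cls(**d)


@dataclass
class SimulationState:
    """Mutable state advanced by :func:`simulation_step`."""

    time: float
    cells: CellPopulation
    fields: list[SoluteGrid]
    medium: MediumDefinition
    geometry: DomainGeometry
    rng: np.random.Generator
    config: SimulationConfig
    next_id: int = 0
    biomass: BiomassGrid | None = None

    def field_values(self) -> dict[str, np.ndarray]:
        return {f.spec.name: f.values for f in self.fields}


@dataclass
class SimulationResult:
    """Snapshots plus a tidy per-timepoint metrics table."""

    config: SimulationConfig
    snapshots: list[tuple[float, CellPopulation]]
    metrics: pd.DataFrame
    final_state: SimulationState

    @property
    def final_counts(self) -> dict[str, int]:
        pop = self.snapshots[-1][1]
        return {"R": pop.count("R"), "S": pop.count("S")}


def initial_state(config: SimulationConfig) -> SimulationState:
    """Seed the simulation: inoculate cells and initialise solute fields."""
    from .inoculation import InoculumSpec, make_inoculum

    rng = np.random.default_rng(config.seed)
    medium = config.build_medium()
    spec = InoculumSpec(n_R=config.n_R, n_S=config.n_S,
                        arrangement=config.arrangement,
                        initial_mass=config.division_mass / 2.0,
                        width=config.geometry.width)
    cells = make_inoculum(spec, rng, density=config.density_g_per_L)
    fields = make_fields(medium, config.geometry)
    state = SimulationState(time=0.0, cells=cells, fields=fields,
                            medium=medium, geometry=config.geometry, rng=rng,
                            config=config, next_id=len(cells))
    _refresh_antibiotic_bulk(state)
    return state


def _refresh_antibiotic_bulk(state: SimulationState) -> None:
    """Antibiotic appears in the bulk only after the configured start time."""
    cfg = state.config
    active = state.time >= cfg.antibiotic_start_time - 1e-12
    for f in state.fields:
        if f.spec.name == "A":
            f.bulk_override = cfg.antibiotic_bulk if active else 0.0


def _growth_rate_grids(state: SimulationState) -> dict[str, np.ndarray]:
    """Per-voxel specific growth rate (1/h) of each lineage."""
    conc = state.field_values()
    out = {}
    for label in ("R", "S"):
        total = np.zeros((state.geometry.ny, state.geometry.nx))
        for reaction in state.medium.reactions_of(label):
            total += reaction_rate_per_biomass(reaction, conc)
        out[label] = total
    return out


def grow_cells(state: SimulationState, dt: float) -> CellPopulation:
    """Multiply each cell's mass by exp(mu * dt) at its local conditions."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    cells = state.cells
    if len(cells) == 0:
        return cells
    h = state.geometry.grid_spacing
    ix = np.floor(cells.x / h).astype(int) % state.geometry.nx
    iy = np.minimum(np.floor(cells.y / h).astype(int), state.geometry.ny - 1)
    rates = _growth_rate_grids(state)
    mu = np.where(cells.mask("R"), rates["R"][iy, ix], rates["S"][iy, ix])
    cells.mass *= np.exp(mu * dt)
    return cells


def divide_cells(state: SimulationState) -> CellPopulation:
    """Split every cell at or above the division mass into two daughters.

    Mass fractions f and 1-f with f ~ U(0.45, 0.55); daughters placed at
    +/- (parent radius / 2) along a uniformly random direction.  Total
    mass is conserved exactly.
    """
    cells = state.cells
    cfg = state.config
    m_div = cfg.division_mass
    width = state.geometry.width
    while True:
        idx = np.nonzero(cells.mass >= m_div)[0]
        if idx.size == 0:
            break
        f = state.rng.uniform(0.45, 0.55, size=idx.size)
        theta = state.rng.uniform(0.0, 2.0 * np.pi, size=idx.size)
        parent_r = radius_from_mass(cells.mass[idx], cells.density)
        ox = 0.5 * parent_r * np.cos(theta)
        oy = 0.5 * parent_r * np.sin(theta)
        m1 = f * cells.mass[idx]
        m2 = cells.mass[idx] - m1
        n_new = idx.size
        new_ids = np.arange(state.next_id, state.next_id + 2 * n_new)
        state.next_id += 2 * n_new
        # parent slot becomes daughter 1; daughter 2 appended
        d2 = CellPopulation(
            ids=new_ids[n_new:], species=cells.species[idx],
            x=np.mod(cells.x[idx] - ox, width), y=cells.y[idx] - oy,
            mass=m2, density=cells.density)
        cells.ids[idx] = new_ids[:n_new]
        cells.x[idx] = np.mod(cells.x[idx] + ox, width)
        cells.y[idx] = cells.y[idx] + oy
        cells.mass[idx] = m1
        cells.ids = np.concatenate([cells.ids, d2.ids])
        cells.species = np.concatenate([cells.species, d2.species])
        cells.x = np.concatenate([cells.x, d2.x])
        cells.y = np.concatenate([cells.y, d2.y])
        cells.mass = np.concatenate([cells.mass, d2.mass])
    radius = cells.radius
    below = cells.y < radius
    cells.y[below] = 2.0 * radius[below] - cells.y[below]  # reflect
    return cells


def relax_overlaps(state: SimulationState) -> CellPopulation:
    """Shove overlapping cells apart (see :mod:`duofilm.mechanics`)."""
    relax_overlaps_population(state.cells, state.geometry.width)
    return state.cells


def simulation_step(state: SimulationState, dt: float) -> SimulationState:
    """Solve solutes, then grow / divide / shove and advance the clock.

    ``dt = 0`` only refreshes the solute fields.
    """
    if dt < 0:
        raise ConfigurationError("dt must be non-negative")
    _refresh_antibiotic_bulk(state)
    state.biomass = rasterize_biomass(state.cells, state.geometry)
    solve_pseudo_steady_state(state.fields, state.biomass, state.medium,
                              tol=state.config.solver_tol)
    if dt == 0:
        return state
    grow_cells(state, dt)
    divide_cells(state)
    relax_overlaps(state)
    state.time += dt
    return state


def _metrics_record(state: SimulationState) -> dict:
    cells = state.cells
    biomass = state.biomass or rasterize_biomass(cells, state.geometry)
    s_R = _metrics.segregation_index(cells, focal_species="R",
                                     width=state.geometry.width)
    return {
        "time_h": state.time,
        "count_R": cells.count("R"), "count_S": cells.count("S"),
        "biomass_R_fg": cells.total_mass("R"),
        "biomass_S_fg": cells.total_mass("S"),
        "s_R": s_R,
        "biofilm_height_um": biofilm_height(biomass),
    }


def run_simulation(config: SimulationConfig,
                   progress: Callable[[SimulationState], None] | None = None,
                   ) -> SimulationResult:
    """Run from t = 0 to ``duration_h``, recording periodic snapshots.

    Deterministic for a fixed config (including seed): repeated runs
    produce identical outputs.
    """
    state = initial_state(config)
    if config.closed_system:
        return _run_closed_system(config, state, progress)
    dt = config.dt_h
    n_steps = int(round(config.duration_h / dt))
    snap_every = max(int(round(config.snapshot_every_h / dt)), 1)
    simulation_step(state, 0.0)  # bring fields to steady state at t = 0
    snapshots = [(0.0, state.cells.copy())]
    records = [_metrics_record(state)]
    for step in range(1, n_steps + 1):
        simulation_step(state, dt)
        if step % snap_every == 0 or step == n_steps:
            snapshots.append((state.time, state.cells.copy()))
            records.append(_metrics_record(state))
            if progress is not None:
                progress(state)
    return SimulationResult(config=config, snapshots=snapshots,
                            metrics=pd.DataFrame.from_records(records),
                            final_state=state)


def _run_closed_system(config: SimulationConfig, state: SimulationState,
                       progress=None) -> SimulationResult:
    """Sealed-microcosm variant: no bulk exchange, finite well-mixed nutrient.

    The nutrient pool is uniform over the domain; each step the pool is
    decremented by exactly (biomass gained) * (1/Y), so nutrient plus
    yield-weighted biomass is conserved to round-off.  Used to audit the
    growth/stoichiometry coupling.
    """
    geom = config.geometry
    volume = geom.width * geom.height  # um^3 (unit depth)
    pool = {f.spec.name: (config.initial_nutrient
                          if config.initial_nutrient is not None
                          and f.spec.bulk_value > 0 else f.spec.bulk_value)
            for f in state.fields}
    dt = config.dt_h
    n_steps = int(round(config.duration_h / dt))
    snap_every = max(int(round(config.snapshot_every_h / dt)), 1)

    def apply_pool():
        for f in state.fields:
            f.values[:] = pool[f.spec.name]

    apply_pool()
    state.biomass = rasterize_biomass(state.cells, geom)
    snapshots = [(0.0, state.cells.copy())]
    records = [_metrics_record(state)]
    for step in range(1, n_steps + 1):
        conc = {name: np.array(v) for name, v in pool.items()}
        for label in ("R", "S"):
            m = state.cells.mask(label)
            if not np.any(m):
                continue
            reactions = state.medium.reactions_of(label)
            mu = sum(float(reaction_rate_per_biomass(r, conc))
                     for r in reactions)
            if mu <= 0:
                continue
            gain = state.cells.mass[m] * (np.exp(mu * dt) - 1.0)
            total_gain = float(gain.sum())
            # consumption demand per solute, split across reactions
            demand = {}
            for r in reactions:
                share = float(reaction_rate_per_biomass(r, conc)) / mu
                for sname, coeff in r.stoichiometry.items():
                    if coeff < 0:
                        demand[sname] = demand.get(sname, 0.0) \
                            + (-coeff) * share * total_gain / volume
            factor = 1.0
            for sname, need in demand.items():
                if need > pool[sname]:
                    factor = min(factor, pool[sname] / need)
            state.cells.mass[m] += factor * gain
            for sname, need in demand.items():
                pool[sname] = max(pool[sname] - factor * need, 0.0)
        divide_cells(state)
        relax_overlaps(state)
        state.time += dt
        apply_pool()
        state.biomass = rasterize_biomass(state.cells, geom)
        if step % snap_every == 0 or step == n_steps:
            snapshots.append((state.time, state.cells.copy()))
            rec = _metrics_record(state)
            rec.update({f"pool_{k}": v for k, v in pool.items()})
            records.append(rec)
            if progress is not None:
                progress(state)
    return SimulationResult(config=config, snapshots=snapshots,
                            metrics=pd.DataFrame.from_records(records),
                            final_state=state)
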
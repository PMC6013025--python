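"""Pseudo-steady-state reaction-diffusion solver on a 2D grid.

Solutes diffuse from a well-mixed bulk compartment located above the
biofilm.  Everything higher than the biofilm front plus a boundary layer
is clamped at the bulk concentration (Dirichlet); the substratum is
impermeable (no flux) and the lateral edges wrap periodically.  Because
solute diffusion is fast relative to biomass growth, the coupled
diffusion-reaction system

    D * laplacian(C_s) + r_s(C, X) = 0        for every solute s

is solved to steady state at each biomass step.

Numerics: Picard iteration over the coupled solutes.  At each pass the
sink terms of one solute are linearised in that solute's own
concentration (factoring out its Monod factor where present, otherwise
limiting consumption by availability), producing a diagonally dominant
M-matrix that is solved directly; positivity of the iterates follows
from the matrix structure, with no truncation needed.  The previous
step's fields serve as warm starts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

try:  # optional acceleration of the inner linear solves
    from ._sor import sor_solve as _sor_solve
except ImportError:  # pragma: no cover - numba not installed
    _sor_solve = None

from .cells import CellPopulation
from .model import (ConfigurationError, MediumDefinition, StateError,
                    reaction_rate_per_biomass, solute_source_terms)

__all__ = [
    "DomainGeometry", "BiomassGrid", "SoluteGrid", "NumericalError",
    "rasterize_biomass", "locate_front_and_clamp",
    "solve_pseudo_steady_state", "make_fields", "biofilm_height",
]

#: relative floor (vs. the solute's scale) below which availability-limited
#: sinks are linearised; keeps depleted zones non-negative.
_AVAIL_FLOOR = 1e-3


class NumericalError(RuntimeError):
    """Solver failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (final relative residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class DomainGeometry:
    """Rectangular 2D domain of unit depth, lateral period = width."""

    width: float = 258.0          # um
    height: float = 258.0         # um
    grid_spacing: float = 2.0     # um
    boundary_layer: float = 40.0  # um

    def __post_init__(self) -> None:
        h = self.grid_spacing
        if h <= 0:
            raise ConfigurationError("grid spacing must be positive")
        for name in ("width", "height"):
            v = getattr(self, name)
            if v <= 0 or abs(v / h - round(v / h)) > 1e-9:
                raise ConfigurationError(
                    f"{name} must be a positive integer multiple of the "
                    "grid spacing")
        if self.boundary_layer < h:
            raise ConfigurationError(
                "boundary layer must be at least one grid spacing")

    @property
    def nx(self) -> int:
        return int(round(self.width / self.grid_spacing))

    @property
    def ny(self) -> int:
        return int(round(self.height / self.grid_spacing))

    @property
    def n_boundary_layer(self) -> int:
        return int(np.ceil(self.boundary_layer / self.grid_spacing - 1e-12))

    @property
    def voxel_volume(self) -> float:
        """um^3 (unit depth)."""
        return self.grid_spacing ** 2


@dataclass
class BiomassGrid:
    """Per-species biomass concentration (g/L) on the solute lattice."""

    geometry: DomainGeometry
    X_R: np.ndarray
    X_S: np.ndarray

    @property
    def occupied_rows(self) -> np.ndarray:
        return np.any((self.X_R > 0) | (self.X_S > 0), axis=1)

    @property
    def front_row(self) -> int:
        """Index of the highest occupied voxel row, -1 if empty."""
        occ = np.nonzero(self.occupied_rows)[0]
        return int(occ[-1]) if occ.size else -1

    def as_mapping(self, n_rows: int | None = None) -> dict[str, np.ndarray]:
        sl = slice(None) if n_rows is None else slice(0, n_rows)
        return {"R": self.X_R[sl], "S": self.X_S[sl]}


@dataclass
class SoluteGrid:
    """Concentration field of one solute (g/L) on the lattice."""

    spec: "SoluteSpecLike"
    values: np.ndarray
    bulk_override: float | None = None

    @property
    def bulk(self) -> float:
        return self.spec.bulk_value if self.bulk_override is None \
            else self.bulk_override


# typing alias only; anything with name/diffusivity/bulk_value works
SoluteSpecLike = object


def make_fields(medium: MediumDefinition,
                geometry: DomainGeometry) -> list[SoluteGrid]:
    """Fresh fields, each uniform at its bulk value."""
    return [SoluteGrid(spec=s,
                       values=np.full((geometry.ny, geometry.nx),
                                      s.bulk_value, dtype=float))
            for s in medium.solutes]


def rasterize_biomass(cells: CellPopulation,
                      geometry: DomainGeometry) -> BiomassGrid:
    """Deposit every cell's mass into its containing voxel.

    Total deposited mass equals total cell mass per species exactly
    (1 fg/um^3 == 1 g/L, so concentration = mass / voxel volume).
    """
    ny, nx = geometry.ny, geometry.nx
    X_R = np.zeros((ny, nx))
    X_S = np.zeros((ny, nx))
    if len(cells):
        h = geometry.grid_spacing
        if np.any(cells.x < 0) or np.any(cells.x > geometry.width):
            raise StateError("cell outside the simulation domain")
        # np.mod can land exactly on width; wrap that edge onto column 0
        ix = np.floor(cells.x / h).astype(int) % nx
        iy = np.floor(cells.y / h).astype(int)
        if np.any(iy < 0) or np.any(iy >= ny):
            raise StateError("cell outside the simulation domain")
        conc = cells.mass / geometry.voxel_volume
        mR = cells.mask("R")
        np.add.at(X_R, (iy[mR], ix[mR]), conc[mR])
        mS = ~mR
        np.add.at(X_S, (iy[mS], ix[mS]), conc[mS])
    return BiomassGrid(geometry=geometry, X_R=X_R, X_S=X_S)


def _n_active_rows(biomass: BiomassGrid) -> int:
    """Rows solved for; everything at or above this index is clamped."""
    geom = biomass.geometry
    return min(biomass.front_row + 1 + geom.n_boundary_layer, geom.ny)


def locate_front_and_clamp(grid: SoluteGrid, biomass: BiomassGrid,
                           geometry: DomainGeometry | None = None
                           ) -> np.ndarray:
    """Clamp nodes above the biofilm front + boundary layer to bulk.

    Returns the boolean mask of clamped nodes and writes the bulk value
    into them.
    """
    geometry = geometry or biomass.geometry
    n_active = _n_active_rows(biomass)
    mask = np.zeros((geometry.ny, geometry.nx), dtype=bool)
    mask[n_active:, :] = True
    grid.values[n_active:, :] = grid.bulk
    return mask


@lru_cache(maxsize=32)
def _neighbour_structure(nx: int, n_rows: int):
    """CSR matrix L with (L C)_i = sum(neighbours) - degree * C_i.

    Periodic laterally, mirrored (no-flux) below row 0; the row above
    ``n_rows - 1`` is Dirichlet and handled through the RHS, but still
    counts towards the degree.
    """
    n = nx * n_rows
    rows, cols, vals = [], [], []
    idx = np.arange(n).reshape(n_rows, nx)
    # lateral (periodic)
    for shift in (1, -1):
        rows.append(idx.ravel())
        cols.append(np.roll(idx, shift, axis=1).ravel())
        vals.append(np.ones(n))
    # vertical
    if n_rows > 1:
        rows.append(idx[1:].ravel())
        cols.append(idx[:-1].ravel())
        vals.append(np.ones(n - nx))
        rows.append(idx[:-1].ravel())
        cols.append(idx[1:].ravel())
        vals.append(np.ones(n - nx))
    deg = np.full((n_rows, nx), 4.0)
    deg[0, :] -= 1.0  # substratum mirror: missing neighbour drops out
    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(-deg.ravel())
    L = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n)).tocsr()
    return L


def _linearised_sources(medium: MediumDefinition, name: str,
                        X: Mapping[str, np.ndarray],
                        C: Mapping[str, np.ndarray],
                        scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Split the net source of solute ``name`` into P - k*C (both >= 0)."""
    shape = C[name].shape
    k = np.zeros(shape)
    P = np.zeros(shape)
    for reaction in medium.reactions:
        nu = reaction.stoichiometry.get(name, 0.0)
        if nu == 0.0:
            continue
        Xa = X.get(reaction.actor)
        if Xa is None or not np.any(Xa):
            continue
        if nu > 0:
            P += nu * reaction_rate_per_biomass(reaction, C) * Xa
            continue
        own_K = dict(reaction.monod_terms).get(name)
        if own_K is not None:
            partial = reaction.max_rate
            for s, Ks in reaction.monod_terms:
                if s != name:
                    partial = partial * C[s] / (C[s] + Ks)
            for s, Ki in reaction.inhibition_terms:
                partial = partial * Ki / (C[s] + Ki)
            # Newton linearisation of the Monod sink around the current
            # iterate: sink(C) ~ sink0 + sink'(C0)(C - C0); the affine
            # remainder (always >= 0) moves to the production side with a
            # negative sign and is compensated by the quadratic term
            q = (-nu) * partial * Xa
            Cn = C[name]
            k += q * own_K / (Cn + own_K) ** 2
            P -= q * Cn ** 2 / (Cn + own_K) ** 2
        else:
            # consumption independent of this solute (growth-coupled
            # antibiotic removal): limit by availability
            sink = (-nu) * reaction_rate_per_biomass(reaction, C) * Xa
            k += sink / np.maximum(C[name], _AVAIL_FLOOR * scale)
    return k, P


def solve_pseudo_steady_state(fields: Sequence[SoluteGrid],
                              biomass: BiomassGrid,
                              medium: MediumDefinition,
                              tol: float = 1e-6,
                              max_outer: int = 500) -> list[SoluteGrid]:
    """Relax all solute fields to their coupled steady state in place.

    ``tol`` bounds the relative change of every field over one outer
    Picard pass; fields enter as warm starts and are updated in place.
    Raises :class:`NumericalError` on non-convergence.
    """
    geom = biomass.geometry
    nx = geom.nx
    n_active = _n_active_rows(biomass)
    dx2 = geom.grid_spacing ** 2
    for f in fields:
        locate_front_and_clamp(f, biomass)
    X = biomass.as_mapping(n_active)
    C = {f.spec.name: f.values[:n_active].copy() for f in fields}
    L = _neighbour_structure(nx, n_active)
    has_biomass = any(np.any(v) for v in X.values())

    worst = np.inf
    history: list[dict[str, np.ndarray]] = []
    for _ in range(max_outer):
        worst = 0.0
        for f in fields:
            name = f.spec.name
            bulk = f.bulk
            scale = max(bulk, float(np.max(C[name])), 1e-30)
            if has_biomass:
                k, P = _linearised_sources(medium, name, X, C, scale)
            else:
                k = P = None
            if not has_biomass or (not np.any(k) and not np.any(P)):
                new = np.full_like(C[name], bulk)  # no sources: uniform bulk
            else:
                coef = f.spec.diffusivity / dx2
                if _sor_solve is not None:
                    new = C[name].copy()
                    omega = 2.0 / (1.0 + np.sin(np.pi / max(nx, n_active)))
                    _sor_solve(new, k, P, coef, bulk, omega,
                               0.02 * tol * scale, 5000)
                else:
                    A = sp.diags(k.ravel()) - coef * L
                    b = P.ravel().copy()
                    b[-nx:] += coef * bulk  # Dirichlet above the active block
                    new = spsolve(A.tocsc(), b).reshape(n_active, nx)
                np.clip(new, 0.0, None, out=new)  # scrub round-off negatives
            worst = max(worst, float(np.max(np.abs(new - C[name]))) / scale)
            C[name] = new
        if worst < tol:
            break
        # Aitken extrapolation: the cross-solute coupling (e.g. the
        # reciprocal by-product loop) makes the outer iteration converge
        # linearly; estimate its ratio from two successive increments and
        # jump towards the fixed point, then resume plain passes.
        history.append({n: v.copy() for n, v in C.items()})
        if len(history) == 3:
            c0, c1, c2 = history
            for name in C:
                d1 = c1[name] - c0[name]
                d2 = c2[name] - c1[name]
                denom = float(np.vdot(d1, d1))
                if denom > 0.0:
                    rho = float(np.vdot(d1, d2)) / denom
                    if 0.0 < rho < 0.97:
                        C[name] = np.clip(c2[name] + rho / (1.0 - rho) * d2,
                                          0.0, None)
            history.clear()
    else:
        raise NumericalError("pseudo-steady-state solve did not converge",
                             worst)
    for f in fields:
        f.values[:n_active] = C[f.spec.name]
    return list(fields)


def steady_state_residual(fields: Sequence[SoluteGrid],
                          biomass: BiomassGrid,
                          medium: MediumDefinition) -> dict[str, float]:
    """Max relative defect |D lap C + source| per solute on active nodes.

    Diagnostic used in testing; the scale is D*bulk/h^2 (or the field
    maximum for solutes without bulk supply).
    """
    geom = biomass.geometry
    n_active = _n_active_rows(biomass)
    dx2 = geom.grid_spacing ** 2
    C = {f.spec.name: f.values for f in fields}
    sources = solute_source_terms(medium, biomass.as_mapping(), C)
    out = {}
    for f in fields:
        v = f.values
        lap = np.empty_like(v)
        lap[:] = np.roll(v, 1, axis=1) + np.roll(v, -1, axis=1) - 2 * v
        interior = np.zeros_like(v)
        interior[1:] += v[:-1]
        interior[0] += v[0]               # substratum mirror
        interior[:-1] += v[1:]
        interior[-1] += f.bulk            # virtual bulk above top row
        lap += interior - 2 * v
        defect = f.spec.diffusivity * lap / dx2 + np.asarray(sources[f.spec.name])
        scale = f.spec.diffusivity * max(f.bulk, float(np.max(v)), 1e-30) / dx2
        out[f.spec.name] = float(np.max(np.abs(defect[:n_active]))) / scale
    return out


def biofilm_height(biomass: BiomassGrid) -> float:
    """Mean over columns of the top surface of the highest occupied voxel (um)."""
    occ = (biomass.X_R > 0) | (biomass.X_S > 0)
    ny, nx = occ.shape
    top = np.where(occ.any(axis=0), occ.shape[0] - np.argmax(occ[::-1], axis=0), 0)
    return float(np.mean(top) * biomass.geometry.grid_spacing)
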
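"""Mechanical relaxation: overlapping cells shove each other apart.

Growth and division create overlaps; relaxation displaces every
overlapping pair symmetrically along its centre line until the largest
overlap falls below a tolerance.  Displacements from all pairs are
accumulated and applied simultaneously each sweep (deterministic without
any pair-ordering convention), slightly over-relaxed to speed up the
diffusive propagation of free space through a packed colony.  The
lateral coordinate wraps periodically and cells are kept above the
substratum (y >= radius).

The neighbour list is built with a KD-tree using an inflated search
radius and reused across sweeps until cells have moved far enough to
invalidate it.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .cells import CellPopulation

__all__ = ["relax_overlaps_arrays", "relax_overlaps_population", "max_overlap"]

#: stop once no pair overlaps by more than this (um)
OVERLAP_TOL = 0.01
MAX_SWEEPS = 5000
#: displacement over-relaxation
OMEGA = 1.2
#: neighbour-list skin (um): pairs further apart than contact by more than
#: this are ignored until the next rebuild
SKIN = 0.6

_Y_BOX = 1e9  # pseudo-periodic box in y, far larger than any biofilm


def _neighbour_pairs(x: np.ndarray, y: np.ndarray, r: np.ndarray,
                     width: float) -> np.ndarray:
    pts = np.column_stack([np.mod(x, width), y])
    tree = cKDTree(pts, boxsize=[width, _Y_BOX])
    return tree.query_pairs(r=2.0 * float(r.max()) + SKIN,
                            output_type="ndarray")


def _overlaps(pairs: np.ndarray, x, y, r, width: float):
    i, j = pairs[:, 0], pairs[:, 1]
    dx = x[j] - x[i]
    dx -= width * np.round(dx / width)  # minimum image
    dy = y[j] - y[i]
    d = np.hypot(dx, dy)
    overlap = r[i] + r[j] - d
    # coincident centres: push apart along +x (deterministic tie-break)
    zero = d == 0
    if np.any(zero):
        dx[zero], dy[zero], d[zero] = 1.0, 0.0, 1.0
    return overlap, dx / d, dy / d


def max_overlap(cells: CellPopulation, width: float) -> float:
    """Largest pairwise overlap depth in the population (um)."""
    x, y, r = cells.x, cells.y, cells.radius
    if len(x) < 2:
        return 0.0
    pairs = _neighbour_pairs(x, y, r, width)
    if len(pairs) == 0:
        return 0.0
    overlap, _, _ = _overlaps(pairs, x, y, r, width)
    return float(max(overlap.max(), 0.0))


def _reflect_substratum(y: np.ndarray, r: np.ndarray) -> None:
    """Bounce cells off the impermeable substratum (keeps y >= r without
    flattening the bottom layer onto one height, which would make shoving
    forces purely horizontal and jam crowded configurations)."""
    below = y < r
    if np.any(below):
        y[below] = 2.0 * r[below] - y[below]


def _sequential_pass(work: np.ndarray, x, y, r, width: float) -> None:
    """One Gauss-Seidel pass in ascending pair order.

    Breaks the symmetric squeezes on which simultaneous displacement can
    stall (each pair sees the other's already-updated position).
    """
    order = np.lexsort((work[:, 1], work[:, 0]))
    for i, j in work[order]:
        dx = x[j] - x[i]
        dx -= width * np.round(dx / width)
        dy = y[j] - y[i]
        d = float(np.hypot(dx, dy))
        ov = r[i] + r[j] - d
        if ov <= 0.0:
            continue
        ux, uy = (dx / d, dy / d) if d > 0 else (1.0, 0.0)
        h = 0.5 * ov
        x[i] -= h * ux
        yi = y[i] - h * uy
        y[i] = 2.0 * r[i] - yi if yi < r[i] else yi
        x[j] += h * ux
        yj = y[j] + h * uy
        y[j] = 2.0 * r[j] - yj if yj < r[j] else yj


def relax_overlaps_arrays(x: np.ndarray, y: np.ndarray, r: np.ndarray,
                          width: float, tol: float = OVERLAP_TOL,
                          max_sweeps: int = MAX_SWEEPS) -> int:
    """Relax overlaps in place; returns the number of sweeps used."""
    n = len(x)
    if n < 2:
        _reflect_substratum(y, r)
        return 0
    pairs = _neighbour_pairs(x, y, r, width)
    work = pairs
    travelled = np.zeros(n)
    fresh = True
    stall_best = np.inf
    stall_count = 0
    for sweep in range(max_sweeps):
        _reflect_substratum(y, r)
        if len(pairs) == 0 or float(travelled.max()) > SKIN / 4.0:
            pairs = _neighbour_pairs(x, y, r, width)
            travelled[:] = 0.0
            fresh = True
            if len(pairs) == 0:
                return sweep
        if fresh:
            # working set: pairs that can touch before the next rebuild
            overlap, _, _ = _overlaps(pairs, x, y, r, width)
            work = pairs[overlap > -SKIN / 2.0]
            fresh = False
            if len(work) == 0:
                return sweep
        overlap, ux, uy = _overlaps(work, x, y, r, width)
        worst = float(overlap.max())
        if worst < tol:
            return sweep
        if worst < stall_best * 0.97:
            stall_best, stall_count = worst, 0
        else:
            stall_count += 1
            if stall_count >= 25:  # jammed: break symmetry sequentially
                _sequential_pass(work, x, y, r, width)
                np.mod(x, width, out=x)
                travelled[:] = np.inf  # force neighbour-list rebuild
                stall_best, stall_count = np.inf, 0
                continue
        active = overlap > 0
        # over-relax small overlaps (accelerates diffusive propagation of
        # free space) but never overshoot touching by more than tol/2
        ov = overlap[active]
        half = 0.5 * np.minimum(OMEGA * ov, ov + 0.5 * tol)
        i = work[active, 0]
        j = work[active, 1]
        ddx = np.zeros(n)
        ddy = np.zeros(n)
        np.add.at(ddx, i, -half * ux[active])
        np.add.at(ddy, i, -half * uy[active])
        np.add.at(ddx, j, half * ux[active])
        np.add.at(ddy, j, half * uy[active])
        x += ddx
        y += ddy
        travelled += np.hypot(ddx, ddy)
        np.mod(x, width, out=x)
    _reflect_substratum(y, r)
    warnings.warn(
        "shoving relaxation did not settle below tolerance within "
        f"{max_sweeps} sweeps", RuntimeWarning, stacklevel=2)
    return max_sweeps


def relax_overlaps_population(cells: CellPopulation, width: float,
                              tol: float = OVERLAP_TOL,
                              max_sweeps: int = MAX_SWEEPS) -> int:
    return relax_overlaps_arrays(cells.x, cells.y, cells.radius, width,
                                 tol=tol, max_sweeps=max_sweeps)
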
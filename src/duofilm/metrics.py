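"""Analysis quantities: census, segregation index, ecological outcomes.

The segregation index of the focal lineage (here R) measures how
spatially assorted it is from its partner:

    s_R = (p_R_local - p_R_global) / (1 - p_R_global)

where ``p_R_global`` is the fraction of R cells in the whole population
and ``p_R_local`` averages, over all R cells, the fraction of same-type
cells among each cell's neighbours within a 10 um radius (the focal cell
itself excluded; cells without neighbours are dropped from the average).
s ~ 0 indicates random mixing, s ~ 1 complete segregation; negative
values indicate over-dispersion (unlike neighbours preferred).

Ecological outcomes follow the coculture-minus-monoculture logic: a
lineage benefits from its partner when it reaches higher numbers in
coculture than alone.  The antibiotic response statistics compare
cocultures across antibiotic levels (competitive release vs. mutualistic
suppression) and susceptible performance across culture compositions at
the same antibiotic level (cross-species phenotypic resistance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cells import Cell, CellPopulation

__all__ = [
    "MetricsRecord", "OutcomeSummary", "local_proportion",
    "segregation_index", "ecological_outcome", "antibiotic_response",
    "solute_height_profile",
]

DEFAULT_NEIGHBOURHOOD_RADIUS = 10.0  # um

_Y_BOX = 1e9


@dataclass(frozen=True)
class MetricsRecord:
    """Per-timepoint census of one simulation."""

    time_h: float
    count_R: int
    count_S: int
    biomass_R_fg: float
    biomass_S_fg: float
    s_R: float
    biofilm_height_um: float


@dataclass(frozen=True)
class OutcomeSummary:
    """Outcome statistics in cells; labels derived from their signs."""

    delta_R_coculture_effect: float | None = None
    delta_S_coculture_effect: float | None = None
    release_statistic: float | None = None
    cross_protection_statistic: float | None = None
    classification: str = ""


def _as_population(cells) -> CellPopulation:
    if isinstance(cells, CellPopulation):
        return cells
    return CellPopulation.from_cells(cells)


def _wrapped_distance(dx: np.ndarray, width: float | None) -> np.ndarray:
    if width is not None:
        dx = dx - width * np.round(dx / width)
    return dx


def local_proportion(cells, focal: Cell,
                     radius: float = DEFAULT_NEIGHBOURHOOD_RADIUS,
                     width: float | None = None) -> float:
    """Fraction of same-type cells among the focal cell's neighbours.

    Neighbours are all other cells within ``radius``; returns NaN when
    the focal cell has no neighbour in range.
    """
    if radius <= 0:
        raise ValueError("neighbourhood radius must be positive")
    pop = _as_population(cells)
    others = pop.ids != focal.id
    if not np.any(pop.ids == focal.id):
        raise ValueError("focal cell is not part of the population")
    dx = _wrapped_distance(pop.x[others] - focal.x, width)
    dy = pop.y[others] - focal.y
    in_range = np.hypot(dx, dy) <= radius
    n_d = int(np.count_nonzero(in_range))
    if n_d == 0:
        return float("nan")
    same = pop.species[others][in_range] == focal.species
    return float(np.count_nonzero(same)) / n_d


def segregation_index(cells, focal_species: str = "R",
                      radius: float = DEFAULT_NEIGHBOURHOOD_RADIUS,
                      width: float | None = None) -> float:
    """Segregation index of the focal lineage; NaN when undefined.

    Undefined when the population holds fewer than two lineages or no
    focal cell has any neighbour in range.  Lateral distances wrap
    periodically when ``width`` is given.
    """
    if radius <= 0:
        raise ValueError("neighbourhood radius must be positive")
    pop = _as_population(cells)
    n = len(pop)
    focal_mask = pop.species == focal_species
    n_focal = int(np.count_nonzero(focal_mask))
    if n_focal == 0 or n_focal == n:
        return float("nan")
    same_counts = np.zeros(n)
    total_counts = np.zeros(n)
    if width is not None:
        pts = np.column_stack([np.mod(pop.x, width), pop.y])
        tree = cKDTree(pts, boxsize=[width, _Y_BOX])
    else:
        tree = cKDTree(np.column_stack([pop.x, pop.y]))
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        same = pop.species[i] == pop.species[j]
        np.add.at(total_counts, i, 1)
        np.add.at(total_counts, j, 1)
        np.add.at(same_counts, i, same)
        np.add.at(same_counts, j, same)
    with np.errstate(invalid="ignore"):
        p_local = same_counts / total_counts
    p_local_focal = p_local[focal_mask]
    defined = ~np.isnan(p_local_focal)
    if not np.any(defined):
        return float("nan")
    p_local_mean = float(np.mean(p_local_focal[defined]))
    p_global = n_focal / n
    return (p_local_mean - p_global) / (1.0 - p_global)


def _counts_at(series, t: float) -> tuple[float, float]:
    """(count_R, count_S) at the timepoint closest to t (within 1e-6 h)."""
    df = series.metrics if hasattr(series, "metrics") else series
    times = df["time_h"].to_numpy(dtype=float)
    i = int(np.argmin(np.abs(times - t)))
    if abs(times[i] - t) > 1e-6:
        raise ValueError(f"no record at t = {t} h (closest: {times[i]} h)")
    row = df.iloc[i]
    return float(row["count_R"]), float(row["count_S"])


def _check_matching(configs: Sequence, attrs: Iterable[str]) -> None:
    configs = [c for c in configs if c is not None]
    for attr in attrs:
        vals = {getattr(c, attr) for c in configs}
        if len(vals) > 1:
            raise ValueError(f"runs being compared differ in {attr!r}: {vals}")


def _config_of(series):
    return getattr(series, "config", None)


def ecological_outcome(co_timeseries, monoR_timeseries, monoS_timeseries,
                       t: float) -> OutcomeSummary:
    """Coculture-minus-monoculture cell-count differences at time t.

    Both positive: the lineages are mutualists; both negative:
    competitors; mixed signs: exploitation of one by the other.
    """
    _check_matching([_config_of(s) for s in
                     (co_timeseries, monoR_timeseries, monoS_timeseries)],
                    ("medium", "antibiotic_bulk", "cost", "alpha"))
    R_co, S_co = _counts_at(co_timeseries, t)
    R_mono, _ = _counts_at(monoR_timeseries, t)
    _, S_mono = _counts_at(monoS_timeseries, t)
    dR = R_co - R_mono
    dS = S_co - S_mono
    if dR > 0 and dS > 0:
        label = "mutualists"
    elif dR < 0 and dS < 0:
        label = "competitors"
    elif dR == 0 and dS == 0:
        label = "neutral"
    else:
        label = "exploitation"
    return OutcomeSummary(delta_R_coculture_effect=dR,
                          delta_S_coculture_effect=dS,
                          classification=label)


def antibiotic_response(co_at_A, co_at_zero, monoS_at_A,
                        t: float) -> OutcomeSummary:
    """Antibiotic-response statistics at time t.

    release = R_co[A>0] - R_co[A=0]  (positive: competitive release of R,
    negative: mutualistic suppression of R);
    cross-protection = S_co[A>0] - S_mono[A>0]  (positive: the susceptible
    lineage does better under antibiotic next to its partner than alone).
    """
    _check_matching([_config_of(co_at_A), _config_of(co_at_zero)],
                    ("medium", "cost", "alpha"))
    _check_matching([_config_of(co_at_A), _config_of(monoS_at_A)],
                    ("medium", "antibiotic_bulk", "cost", "alpha"))
    R_A, S_A = _counts_at(co_at_A, t)
    R_0, _ = _counts_at(co_at_zero, t)
    _, S_mono = _counts_at(monoS_at_A, t)
    release = R_A - R_0
    protection = S_A - S_mono
    if release > 0:
        label = "competitive_release"
    elif release < 0:
        label = "mutualistic_suppression"
    else:
        label = "neutral"
    return OutcomeSummary(release_statistic=release,
                          cross_protection_statistic=protection,
                          classification=label)


def solute_height_profile(field, geometry=None) -> pd.DataFrame:
    """Laterally averaged concentration per grid row.

    Returns columns ``height_um`` (voxel-centre heights) and
    ``mean_conc`` (g/L).
    """
    values = field.values if hasattr(field, "values") else np.asarray(field)
    h = geometry.grid_spacing if geometry is not None else 1.0
    heights = (np.arange(values.shape[0]) + 0.5) * h
    return pd.DataFrame({"height_um": heights,
                         "mean_conc": values.mean(axis=1)})
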
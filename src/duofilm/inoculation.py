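"""Initial conditions: seeding cells on the substratum.

Two arrangements are used throughout: ``random`` (both lineages
scattered independently along the surface, i.e. well mixed) and
``segregated`` (R in the left half-domain, S in the right, as two
contiguous blocks).  Ratio sweeps vary the initial fraction of S at a
fixed total inoculum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import (DEFAULT_DENSITY, CellPopulation, mass_from_radius,
                    radius_from_mass)
from .mechanics import relax_overlaps_population
from .model import ConfigurationError

__all__ = ["InoculumSpec", "make_inoculum", "ratio_sweep_specs"]

#: the substratum can stack only so many layers of founder cells before
#: the seeding stops being a surface inoculation
_MAX_PACKING_LAYERS = 4.0


@dataclass(frozen=True)
class InoculumSpec:
    """Counts, arrangement and per-cell mass of the founding population."""

    n_R: int = 120
    n_S: int = 120
    arrangement: str = "random"
    initial_mass: float | None = None   # fg; default: half the division mass
    width: float = 258.0                # um

    def __post_init__(self) -> None:
        if self.n_R < 0 or self.n_S < 0 or self.n_R + self.n_S < 1:
            raise ConfigurationError(
                "inoculum needs non-negative counts summing to >= 1")
        if self.arrangement not in ("random", "segregated"):
            raise ConfigurationError(
                f"unknown arrangement {self.arrangement!r}")


def make_inoculum(spec: InoculumSpec, rng: np.random.Generator,
                  density: float = DEFAULT_DENSITY) -> CellPopulation:
    """Place the founding cells on the substratum and resolve overlaps.

    Random arrangement: every cell draws an independent Uniform(0, width)
    lateral position (species interleaved at random by construction).
    Segregated: R cells uniform in [0, width/2), S in [width/2, width).
    All cells start at y = radius; shoving then resolves overlaps, which
    may lift some cells slightly off the surface in crowded inocula.
    """
    if spec.initial_mass is not None:
        mass0 = spec.initial_mass
    else:
        mass0 = mass_from_radius(1.0, density) / 2.0
    r0 = float(radius_from_mass(mass0, density))
    n = spec.n_R + spec.n_S
    if n * 2.0 * r0 > _MAX_PACKING_LAYERS * spec.width:
        raise ConfigurationError(
            f"cannot seed {n} cells of radius {r0:.2f} um on a "
            f"{spec.width} um substratum")
    species = np.array(["R"] * spec.n_R + ["S"] * spec.n_S, dtype="U1")
    if spec.arrangement == "random":
        x = rng.uniform(0.0, spec.width, size=n)
    else:
        x = np.empty(n)
        x[: spec.n_R] = rng.uniform(0.0, spec.width / 2.0, size=spec.n_R)
        x[spec.n_R:] = rng.uniform(spec.width / 2.0, spec.width,
                                   size=spec.n_S)
    # tiny vertical jitter: a perfectly collinear crowd is mechanically
    # degenerate (all shoving forces stay horizontal), so crowded inocula
    # could never stack
    y = r0 + rng.uniform(0.0, 1e-2, size=n)
    cells = CellPopulation(ids=np.arange(n), species=species, x=x,
                           y=y, mass=np.full(n, float(mass0)),
                           density=density)
    relax_overlaps_population(cells, spec.width)
    return cells


def ratio_sweep_specs(total: int, proportions_S, arrangements,
                      width: float = 258.0,
                      initial_mass: float | None = None) -> list[InoculumSpec]:
    """Cartesian product of S proportions and arrangements at fixed total.

    Counts are rounded to the nearest integer while preserving the total.
    """
    specs = []
    for p in proportions_S:
        if not 0.0 < p < 1.0:
            raise ConfigurationError("proportions must lie strictly in (0, 1)")
        n_S = int(round(p * total))
        for arrangement in arrangements:
            specs.append(InoculumSpec(n_R=total - n_S, n_S=n_S,
                                      arrangement=arrangement, width=width,
                                      initial_mass=initial_mass))
    return specs
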
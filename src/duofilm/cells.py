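"""Cell representation: individual records and the array-backed population.

Cells are circular agents of unit depth (1 um); mass and radius are linked
through a fixed cytoplasm density rho via ``m = rho * pi * r^2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = ["Cell", "CellPopulation", "radius_from_mass", "mass_from_radius",
           "DEFAULT_DENSITY", "DEFAULT_DIVISION_RADIUS"]

#: cytoplasm density, g/L == fg/um^3
DEFAULT_DENSITY = 200.0
#: cells divide when their radius reaches this value (um)
DEFAULT_DIVISION_RADIUS = 1.0

SPECIES_LABELS = ("R", "S")


def radius_from_mass(mass, density: float = DEFAULT_DENSITY):
    """Radius (um) of a unit-depth cell of given mass (fg)."""
    return np.sqrt(np.asarray(mass, dtype=float) / (density * np.pi))


def mass_from_radius(radius, density: float = DEFAULT_DENSITY):
    """Mass (fg) of a unit-depth cell of given radius (um)."""
    return density * np.pi * np.asarray(radius, dtype=float) ** 2


@dataclass
class Cell:
    """A single agent: identity, lineage, centre position and mass."""

    id: int
    species: str
    x: float
    y: float
    mass: float

    def radius(self, density: float = DEFAULT_DENSITY) -> float:
        return float(radius_from_mass(self.mass, density))


class CellPopulation:
    """Array-backed collection of cells (structure-of-arrays).

    Primary container used by the engine; converts to/from ``Cell``
    records and tidy DataFrames at the edges.
    """

    def __init__(self, ids=None, species=None, x=None, y=None, mass=None,
                 density: float = DEFAULT_DENSITY):
        self.ids = np.asarray(ids if ids is not None else [], dtype=np.int64)
        self.species = np.asarray(species if species is not None else [],
                                  dtype="U1")
        self.x = np.asarray(x if x is not None else [], dtype=float)
        self.y = np.asarray(y if y is not None else [], dtype=float)
        self.mass = np.asarray(mass if mass is not None else [], dtype=float)
        self.density = float(density)
        n = len(self.ids)
        if not (len(self.species) == len(self.x) == len(self.y)
                == len(self.mass) == n):
            raise ValueError("inconsistent array lengths")

    # -- construction -------------------------------------------------
    @classmethod
    def from_cells(cls, cells: Iterable[Cell],
                   density: float = DEFAULT_DENSITY) -> "CellPopulation":
        cells = list(cells)
        return cls(ids=[c.id for c in cells],
                   species=[c.species for c in cells],
                   x=[c.x for c in cells], y=[c.y for c in cells],
                   mass=[c.mass for c in cells], density=density)

    def copy(self) -> "CellPopulation":
        return CellPopulation(self.ids.copy(), self.species.copy(),
                              self.x.copy(), self.y.copy(), self.mass.copy(),
                              density=self.density)

    # -- views ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[Cell]:
        for i in range(len(self)):
            yield Cell(int(self.ids[i]), str(self.species[i]),
                       float(self.x[i]), float(self.y[i]),
                       float(self.mass[i]))

    @property
    def radius(self) -> np.ndarray:
        return radius_from_mass(self.mass, self.density)

    def mask(self, label: str) -> np.ndarray:
        return self.species == label

    def count(self, label: str) -> int:
        return int(np.count_nonzero(self.species == label))

    def total_mass(self, label: str | None = None) -> float:
        if label is None:
            return float(self.mass.sum())
        return float(self.mass[self.mask(label)].sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.ids, "species": self.species,
            "x_um": self.x, "y_um": self.y, "mass_fg": self.mass,
            "radius_um": self.radius,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       density: float = DEFAULT_DENSITY) -> "CellPopulation":
        return cls(ids=df["cell_id"].to_numpy(),
                   species=df["species"].to_numpy(),
                   x=df["x_um"].to_numpy(), y=df["y_um"].to_numpy(),
                   mass=df["mass_fg"].to_numpy(), density=density)
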
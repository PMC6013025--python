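import numpy as np
import pytest

from duofilm.cells import CellPopulation
from duofilm.model import ParameterSet, build_medium
from duofilm.solver import DomainGeometry


@pytest.fixture
def params():
    return ParameterSet()


@pytest.fixture
def small_geometry():
    return DomainGeometry(width=40.0, height=60.0, grid_spacing=2.0,
                          boundary_layer=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def population(specs, density=200.0):
    """Build a CellPopulation from (species, x, y, mass) tuples."""
    return CellPopulation(
        ids=np.arange(len(specs)),
        species=[s[0] for s in specs],
        x=[s[1] for s in specs], y=[s[2] for s in specs],
        mass=[s[3] for s in specs], density=density)


@pytest.fixture
def exploitation_medium(params):
    return build_medium("exploitation_competition", params)
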
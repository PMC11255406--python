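"""Shared fixtures: small synthetic landscapes and communities.

Everything is generated at test time from fixed seeds; heavier objects are
session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from bftb_sdm import NicheSpec, simulate_community, simulate_landscape, simulate_species
from bftb_sdm.raster import Grid, RasterGrid


@pytest.fixture(scope="session")
def landscape():
    """Default 60x60 landscape (19 layers, ~88% land)."""
    return simulate_landscape(seed=5)


@pytest.fixture(scope="session")
def small_landscape():
    """30x30 landscape for cheap unit tests."""
    return simulate_landscape(
        extent=(100.0, 18.0, 107.5, 25.5), resolution_arcmin=15.0,
        n_extra_layers=2, seed=13,
    )


@pytest.fixture(scope="session")
def steep_species(small_landscape):
    """A well-sampled virtual species with a steep two-variable niche."""
    return simulate_species(
        small_landscape,
        NicheSpec(betas=(6.0, 6.0), prevalence=0.12),
        n_occurrences=30,
        seed=21,
        name="steep",
    )


@pytest.fixture(scope="session")
def tiny_community(small_landscape):
    """3 MaxEnt-tier + 2 MCP-AT-tier + 1 point-tier species."""
    return simulate_community(small_landscape, (3, 2, 1), seed=17)


@pytest.fixture
def flat_grid():
    """A 10x10 all-land grid at 0.5 degree resolution for hand examples."""
    grid = Grid(west=100.0, south=20.0, resolution=0.5, nrows=10, ncols=10)
    land = RasterGrid(name="land_mask", grid=grid, values=np.ones(grid.shape))
    return grid, land
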
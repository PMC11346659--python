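import numpy as np
import pytest

from barriersim import (GridSpec, IslandState, IslandTemplate,
                        make_island_with_vegetation)


@pytest.fixture
def grid():
    """Small default-geometry lattice (delta=0.1 m, L=4 m)."""
    return GridSpec(12, 12)


@pytest.fixture
def flat_state(grid):
    """All-water state: H=0 everywhere, no vegetation."""
    return IslandState(grid=grid,
                       height=np.zeros(grid.shape, dtype=np.int64),
                       cover=np.zeros((4, *grid.shape)))


def make_flat_island(grid, slabs, cover=None):
    """Uniform island of `slabs` slabs with optional uniform cover array."""
    h = np.full(grid.shape, slabs, dtype=np.int64)
    c = np.zeros((4, *grid.shape))
    if cover is not None:
        for k, v in enumerate(cover):
            c[k] = v
    return IslandState(grid=grid, height=h, cover=c)


@pytest.fixture(scope="session")
def tiny_template():
    """Reduced island template for fast full-pipeline tests."""
    return IslandTemplate(
        grid=GridSpec(60, 160), row_margin=6, taper_rows=4,
        back_margin=64, marsh_width=8, core_start=84, core_end=106,
        platform_end=120, dune_crest=124, beach_start=129, shoreline=140,
        seed=0)


@pytest.fixture(scope="session")
def tiny_island(tiny_template):
    return make_island_with_vegetation(tiny_template)
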
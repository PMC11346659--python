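"""Synthetic islands and wind climates.

No deposited elevation, vegetation, or wind data exist for the Virginia
coast islands the model was built around, so every experiment in this
package runs on generated inputs that reproduce the *structure* those data
have: an elongated north-south barrier island with a beach and foredune
ridge on the ocean (east) side, an interior platform, a low back-barrier
marsh fringe, a grass-dominated upper (northern) half, a woody-shrub core
on a raised interior in the lower half, and a wind climate whose speeds
concentrate in the 6-16 m/s transport window with a prevailing onshore
(easterly) component.

The template's default covers and zonation follow the species' viable
elevation bands: dune grasses on the ridge, sparse *Spartina patens*
patches on the platform, *S. alterniflora* on the marsh fringe, *Morella*
only on the raised lower-half core (the shrub needs >= 1.5 m).  The beach
seaward of the ridge crest is left bare, as a constantly reworked surface.

Everything is seed-deterministic and validated against the full state
invariants before being returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import GridSpec, IslandState, N_SPECIES, check_state
from .vegetation import (DEFAULT_SPECIES, DEFAULT_TOTAL_COVER_CAP, WOODY,
                         crowding_adjust)
from .aeolian import COMPASS, WindRecord


@dataclass(frozen=True)
class IslandTemplate:
    """Geometry and vegetation zonation of the generated island.

    Columns run west (0, back-barrier lagoon) to east (ocean).  All column
    parameters are cell indices on the template grid; heights in meters.
    """

    grid: GridSpec = field(default_factory=lambda: GridSpec(200, 560))
    row_margin: int = 10          # water rows at each alongshore tip
    taper_rows: int = 8           # rows over which tip elevation ramps up
    back_margin: int = 464        # lagoon columns: room for decades of rollover
    marsh_width: int = 10         # marsh fringe columns
    platform_end: int = 520       # first dune column
    dune_crest: int = 524         # ridge crest column
    beach_start: int = 529        # first beach column (seaward ridge toe)
    shoreline: int = 540          # last subaerial column
    marsh_height: float = 0.3
    platform_height: float = 1.6
    dune_height: float = 2.8
    core_height: float = 2.0      # raised lower-half interior (shrub zone)
    core_start: int = 484
    core_end: int = 516           # exclusive
    water_depth: float = 1.0      # lagoon/shoreface depth below the island base
    noise_slabs: int = 1          # +/- amplitude of seeded elevation noise
    # vegetation defaults (per-cell cover on occupied cells)
    dune_grass_cover: float = 0.6      # A. breviligulata on the ridge
    dune_patens_cover: float = 0.2
    platform_patens_cover: float = 0.5
    platform_patch_fraction: float = 0.15  # occupancy of platform patches
    marsh_cover: float = 0.6           # S. alterniflora fringe
    woody_cover: float = 0.6           # Morella on the raised core
    core_grass_cover: float = 0.15     # A. breviligulata mixed into the core
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.back_margin
                and self.back_margin + self.marsh_width < self.platform_end
                <= self.dune_crest < self.beach_start <= self.shoreline
                < self.grid.n_cols - 2):
            raise ValueError("island cross-section does not fit in the grid "
                             "with a >=2-cell water margin")
        if self.row_margin < 2 or 2 * self.row_margin >= self.grid.n_rows - 1:
            raise ValueError("island does not fit alongshore with a "
                             ">=2-cell water margin")
        if self.dune_height <= 0:
            raise ValueError("ridge height must be positive")
        if self.water_depth < 0:
            raise ValueError("water_depth must be non-negative")


def _cross_shore_profile(template: IslandTemplate, raised: bool) -> np.ndarray:
    """Piecewise-linear elevation (m) across one row; ``raised`` selects the
    lower-half profile with the elevated shrub core."""
    t = template
    marsh_end = t.back_margin + t.marsh_width
    anchors_c = [t.back_margin - 1, t.back_margin, t.back_margin + 2,
                 marsh_end, marsh_end + 3]
    anchors_z = [0.0, 0.05, t.marsh_height, t.marsh_height, t.platform_height]
    if raised:
        anchors_c += [t.core_start - 3, t.core_start, t.core_end - 1,
                      t.core_end + 2]
        anchors_z += [t.platform_height, t.core_height, t.core_height,
                      t.platform_height]
    anchors_c += [t.platform_end - 1, t.dune_crest, t.beach_start,
                  t.shoreline, t.shoreline + 1]
    anchors_z += [t.platform_height, t.dune_height,
                  0.75 * t.dune_height, 0.05, 0.0]
    cols = np.arange(t.grid.n_cols, dtype=float)
    z = np.interp(cols, anchors_c, anchors_z)
    z[cols < t.back_margin] = 0.0
    z[cols > t.shoreline] = 0.0
    return z


def split_row(template: IslandTemplate) -> int:
    """Row separating the grass-dominated upper half from the woody lower
    half (midpoint of the island's alongshore extent, assigned to upper)."""
    first = template.row_margin
    last = template.grid.n_rows - template.row_margin - 1
    return (first + last) // 2


def make_island(template: IslandTemplate) -> IslandState:
    """Build the initial elevation state (bare of vegetation).

    The cross-shore profile rises from the shoreline to the dune ridge and
    descends to the back-barrier platform and marsh; the lower half carries
    the raised interior core.  The island sits on a substrate raised
    ``water_depth`` meters above the surrounding sea floor (the initial
    sea-level offset), so open water has realistic depth and a stray slab
    deposited into it does not instantly make new land.  Elevations are
    quantized to slabs, seeded noise of +/- ``noise_slabs`` is added to
    subaerial cells, and tip rows taper into the water.
    """
    t = template
    rng = np.random.default_rng(t.seed)
    n, m = t.grid.shape
    upper = _cross_shore_profile(t, raised=False)
    lower = _cross_shore_profile(t, raised=True)
    split = split_row(t)
    elev = np.zeros((n, m))
    first, last = t.row_margin, n - t.row_margin - 1
    for i in range(first, last + 1):
        elev[i] = upper if i <= split else lower
    # taper the tips so the island ends in low ground, not a cliff
    if t.taper_rows > 0:
        ramp = np.linspace(0.3, 1.0, t.taper_rows + 1)[:-1]
        for j, f in enumerate(ramp):
            elev[first + j] *= f
            elev[last - j] *= f
    land = elev > 0
    elev = np.where(land, elev + t.water_depth, 0.0)
    height = np.round(elev / t.grid.slab_thickness).astype(np.int64)
    if t.noise_slabs > 0:
        noise = rng.integers(-t.noise_slabs, t.noise_slabs + 1, size=(n, m))
        height = np.maximum(height + noise * land, 0)
    cover = np.zeros((N_SPECIES, n, m))
    return IslandState(grid=t.grid, height=height, cover=cover,
                       sea_level_offset=t.water_depth)


def make_vegetation(state: IslandState, template: IslandTemplate,
                    species=DEFAULT_SPECIES,
                    total_cap: float = DEFAULT_TOTAL_COVER_CAP) -> IslandState:
    """Populate the four cover grids on an island generated by
    :func:`make_island`, respecting each species' elevation band, the
    upper/lower zonation, and the cover caps (via a crowding pass).
    """
    t = template
    rng = np.random.default_rng(t.seed + 1)
    elev = state.effective_elevation()
    sub = state.subaerial_mask()
    n, m = state.grid.shape
    rows = np.arange(n)[:, None]
    cols = np.arange(m)[None, :]
    split = split_row(t)
    upper_half = rows <= split

    def in_band(k):
        sp = species[k]
        return sub & (elev >= sp.elev_min) & (elev <= sp.elev_max)

    cover = np.zeros_like(state.cover)
    dune_zone = (cols >= t.platform_end) & (cols <= t.shoreline) & \
        (cols < t.beach_start)
    platform_zone = (cols >= t.back_margin + t.marsh_width) & \
        (cols < t.platform_end)
    marsh_zone = (cols >= t.back_margin) & (cols < t.back_margin
                                            + t.marsh_width)
    core_zone = (~upper_half) & (cols >= t.core_start) & (cols < t.core_end)

    cover[0][dune_zone & in_band(0)] = t.dune_grass_cover
    cover[1][dune_zone & in_band(1)] = t.dune_patens_cover
    patches = rng.random((n, m)) < t.platform_patch_fraction
    cover[1][platform_zone & in_band(1) & patches & ~core_zone] = \
        t.platform_patens_cover
    cover[2][marsh_zone & in_band(2)] = t.marsh_cover
    cover[WOODY][core_zone & in_band(WOODY)] = t.woody_cover
    cover[0][core_zone & in_band(0)] = t.core_grass_cover
    cover[WOODY] *= ~upper_half  # zonation rule: no shrub in the upper half

    cover = crowding_adjust(cover, total_cap, species[WOODY].cover_max)
    for k, sp in enumerate(species):
        np.clip(cover[k], 0.0, sp.cover_max, out=cover[k])
    state.cover = cover
    check_state(state, species, total_cap, context="make_vegetation")
    return state


def make_island_with_vegetation(template: IslandTemplate,
                                species=DEFAULT_SPECIES,
                                total_cap: float = DEFAULT_TOTAL_COVER_CAP,
                                ) -> IslandState:
    """Convenience: elevation plus vegetation in one call."""
    return make_vegetation(make_island(template), template, species, total_cap)


@dataclass(frozen=True)
class WindClimate:
    """Weibull wind-speed law plus an 8-point direction distribution.

    The defaults (shape 2, scale 8 m/s) put a majority of draws inside the
    6-16 m/s transport window and exercise every transport-distance class;
    the direction vector favours onshore (E/NE/SE) winds.
    """

    weibull_shape: float = 2.0
    weibull_scale: float = 8.0
    direction_probs: tuple[float, ...] = (
        0.08, 0.15, 0.35, 0.15, 0.08, 0.06, 0.07, 0.06)  # N..NW, COMPASS order

    def __post_init__(self) -> None:
        if self.weibull_scale <= 0 or self.weibull_shape <= 0:
            raise ValueError("Weibull parameters must be positive")
        if len(self.direction_probs) != len(COMPASS):
            raise ValueError("need one probability per compass direction")
        if abs(sum(self.direction_probs) - 1.0) > 1e-9:
            raise ValueError("direction probabilities must sum to 1")


def wind_series(climate: WindClimate, n_steps: int,
                rng: np.random.Generator | int | None = 0,
                ) -> list[WindRecord]:
    """Draw ``n_steps`` independent two-week wind records."""
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    speeds = climate.weibull_scale * rng.weibull(climate.weibull_shape,
                                                size=n_steps)
    dirs = rng.choice(len(COMPASS), size=n_steps, p=climate.direction_probs)
    return [WindRecord(float(s), COMPASS[d]) for s, d in zip(speeds, dirs)]
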
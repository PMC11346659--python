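"""Wind-driven slab transport.

Every two-week step, one wind record (speed + 8-point compass direction, the
meteorological "blowing from" convention) is applied to the whole grid.  Each
subaerial cell with at least one slab loses its top slab with probability

    rho = (1 - PC) * (omega - omega_L) / (omega_H - omega_L)

(zero below the transport threshold ``omega_L``; clipped to [0, 1]), where PC
is the erosion-effective plant cover of the cell.  A moving slab travels a
whole number of cells set by the wind-speed class (1 / 2 / 3 cells for the
6-9 / 9-13 / 13-16 m/s bands) and lands downwind with probability 1/2 or in
either 45-degree off-direction with probability 1/4 each.  Pickups are
decided on the pre-event surface (synchronous update); slabs crossing the
open boundary are lost; deposition into water is allowed and raises the
subaqueous surface.  Winds above ``omega_H`` belong to the storm regime and
the event is skipped (storms are deliberately not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import IslandState

#: compass ring, clockwise from north
COMPASS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

#: (drow, dcol) unit offsets of each compass direction (row 0 = north,
#: high columns = east)
OFFSETS = {
    "N": (-1, 0), "NE": (-1, 1), "E": (0, 1), "SE": (1, 1),
    "S": (1, 0), "SW": (1, -1), "W": (0, -1), "NW": (-1, -1),
}

#: default transport window bounds, m/s
WIND_MIN = 6.0
WIND_MAX = 16.0


@dataclass(frozen=True)
class WindRecord:
    """One sampled two-week wind: speed (m/s) and the direction the wind
    blows *from* (8-point compass)."""

    speed: float
    direction: str

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("wind speed must be non-negative")
        if self.direction not in COMPASS:
            raise ValueError(f"direction must be one of {COMPASS}")


def transport_distance(speed: float, storm_threshold: float = WIND_MAX) -> int:
    """Cells a moving slab travels for a given wind speed.

    0 below 6 m/s, 1 for [6, 9), 2 for [9, 13), 3 for [13, 16].  Speeds above
    the storm threshold are outside the handled regime.
    """
    if speed < 0:
        raise ValueError("wind speed must be non-negative")
    if speed > storm_threshold:
        raise ValueError(f"storm-regime wind ({speed} m/s) not handled")
    if speed < 6.0:
        return 0
    if speed < 9.0:
        return 1
    if speed < 13.0:
        return 2
    return 3


def move_probability(pc, speed: float, wind_min: float = WIND_MIN,
                     wind_max: float = WIND_MAX):
    """Probability that a surface slab is entrained, attenuated by cover.

    rho = (1 - PC) * (omega - omega_L)/(omega_H - omega_L), clipped to [0,1];
    winds below the transport threshold give 0.
    """
    if wind_min >= wind_max:
        raise ValueError("wind_min must be below wind_max")
    frac = (speed - wind_min) / (wind_max - wind_min)
    frac = min(max(frac, 0.0), 1.0)
    return np.clip((1.0 - np.asarray(pc, dtype=float)) * frac, 0.0, 1.0)


def downwind(direction_from: str) -> str:
    """Compass direction a slab travels for wind blowing from ``direction_from``."""
    return COMPASS[(COMPASS.index(direction_from) + 4) % len(COMPASS)]


def _lobes(direction_from: str) -> tuple[str, str, str]:
    """(main, left-off, right-off) destination directions."""
    i = COMPASS.index(downwind(direction_from))
    return (COMPASS[i], COMPASS[(i - 1) % 8], COMPASS[(i + 1) % 8])


def sample_destination_direction(direction_from: str,
                                 rng: np.random.Generator) -> str:
    """Draw a destination direction: downwind with p=1/2, each adjacent
    45-degree direction with p=1/4."""
    main, left, right = _lobes(direction_from)
    u = rng.random()
    if u < 0.5:
        return main
    return left if u < 0.75 else right


def aeolian_event(state: IslandState, wind: WindRecord,
                  rng: np.random.Generator, pc: np.ndarray,
                  wind_min: float = WIND_MIN, wind_max: float = WIND_MAX,
                  log=None) -> int:
    """Apply one two-week wind event in place; returns slabs moved.

    Storm-regime winds (speed > wind_max) skip the event with a logged
    notice rather than raising.
    """
    if wind.speed > wind_max:
        if log is not None:
            log.append(f"storm wind {wind.speed:.1f} m/s skipped")
        return 0
    dist = transport_distance(wind.speed, wind_max)
    if dist == 0:
        return 0
    movable = state.subaerial_mask() & (state.height >= 1)
    rho = move_probability(pc, wind.speed, wind_min, wind_max)
    picked = movable & (rng.random(state.grid.shape) < rho)
    rows, cols = np.nonzero(picked)
    n = rows.size
    if n == 0:
        return 0
    # 50/25/25 destination lobes, one draw per moving slab
    u = rng.random(n)
    lobe = np.where(u < 0.5, 0, np.where(u < 0.75, 1, 2))
    offsets = np.array([OFFSETS[d] for d in _lobes(wind.direction)])
    dr, dc = offsets[lobe, 0], offsets[lobe, 1]
    dest_r = rows + dr * dist
    dest_c = cols + dc * dist
    state.height[rows, cols] -= 1
    inside = ((dest_r >= 0) & (dest_r < state.grid.n_rows)
              & (dest_c >= 0) & (dest_c < state.grid.n_cols))
    np.add.at(state.height, (dest_r[inside], dest_c[inside]), 1)
    return n


__all__ = [
    "COMPASS", "OFFSETS", "WIND_MIN", "WIND_MAX", "WindRecord",
    "transport_distance", "move_probability", "downwind",
    "sample_destination_direction", "aeolian_event",
]
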
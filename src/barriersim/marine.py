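"""Sea-level curves and vegetation-modulated shoreline migration.

Sea level follows a quadratic scenario curve anchored at 1992,

    L(t) = a (t - 1992) + b (t - 1992)^2 + c      [cm above the 1984 datum]

with historic linear growth (b = 0) back-extrapolated through the same
anchor for 1984-1992.  Four named scenarios share a = 0.45 cm/yr and
c = 3.6 cm and differ in the acceleration b: historic (0), low (0.0043),
high (0.0105), highest (0.0157) cm/yr^2.  The annual rise is the first
difference S(t) = L(t) - L(t-1).

Shoreline recession follows a whole-island Bruun-type proportionality
R = B * S.  B may be computed from an island cross-section (shore-zone
lengths, berm heights, closure depths) or, by default, calibrated from an
observed initial retreat rate: B = R_o / S_ref (15 m/yr over 0.45 cm/yr
gives B ~ 3333).

Vegetation attenuates migration through the migration factor M_f of each
alongshore row: the mean effective cover PC over the subaerial cells of a
moving window of 2w+1 rows (all columns, truncated at the grid edge).  The
per-row landward migration is

    R_i = (1 - alpha_f * M_f) * B * S,   alpha_f = 1/M_f if M_f >= 0.5 else 2,

so migration shuts off completely at half cover and scales linearly below
it.  Migration is realized as a rigid landward translation of each row's
elevation and cover profiles (island rollover under an abundant sediment
supply); fractional cells carry over between years so nothing is lost to
rounding.  An erosion-only alternative (ocean-side columns removed, no
translation) is available for users who prefer a fixed back-barrier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import IslandState


@dataclass(frozen=True)
class SLRScenario:
    """Quadratic sea-level curve: cm above the 1984 datum."""

    name: str
    a: float = 0.45        # linear rate, cm/yr
    b: float = 0.0         # acceleration, cm/yr^2
    c: float = 3.6         # level at the anchor year, cm
    accel_start: int = 1992
    datum_year: int = 1984

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("rates a and b must be non-negative")


#: the four named scenarios
SCENARIOS: dict[str, SLRScenario] = {
    "historic": SLRScenario("historic", b=0.0),
    "low": SLRScenario("low", b=0.0043),
    "high": SLRScenario("high", b=0.0105),
    "highest": SLRScenario("highest", b=0.0157),
}


def sea_level(scenario: SLRScenario, year: float) -> float:
    """Sea level L(t) in cm above the 1984 datum."""
    if year < scenario.datum_year:
        raise ValueError(f"year {year} precedes the {scenario.datum_year} datum")
    tau = year - scenario.accel_start
    level = scenario.a * tau + scenario.c
    if year >= scenario.accel_start:
        level += scenario.b * tau * tau
    return level


def slr_increment(scenario: SLRScenario, year: float) -> float:
    """Annual rise S(t) = L(t) - L(t-1), in cm/yr."""
    return sea_level(scenario, year) - sea_level(scenario, year - 1)


@dataclass(frozen=True)
class BruunGeometry:
    """Island cross-section for the whole-island recession coefficient.

    Lengths in meters: island width W, active shore-zone lengths on the
    ocean (L_0) and lagoon (L_L) sides, berm heights B_0/B_L and closure
    depths hb_0/hb_L.
    """

    width: float
    shore_len_ocean: float
    shore_len_lagoon: float
    berm_ocean: float
    depth_ocean: float
    berm_lagoon: float
    depth_lagoon: float

    def __post_init__(self) -> None:
        for v in (self.width, self.shore_len_ocean, self.shore_len_lagoon,
                  self.berm_ocean, self.depth_ocean, self.berm_lagoon,
                  self.depth_lagoon):
            if v < 0:
                raise ValueError("lengths and depths must be non-negative")


def bruun_coefficient(geom: BruunGeometry) -> float:
    """B = (L_0 + W + L_L) / ((B_0 + hb_0) - (B_L + hb_L)), dimensionless."""
    num = geom.shore_len_ocean + geom.width + geom.shore_len_lagoon
    den = (geom.berm_ocean + geom.depth_ocean) - (geom.berm_lagoon
                                                  + geom.depth_lagoon)
    if den == 0:
        raise ValueError("degenerate cross-section: zero denominator")
    return num / den


def calibrate_bruun(initial_retreat: float, ref_rise: float) -> float:
    """B from an observed retreat rate and reference rise (same length unit
    per year for both, e.g. m/yr over m/yr)."""
    if ref_rise <= 0:
        raise ValueError("reference rise must be positive")
    return initial_retreat / ref_rise


@dataclass(frozen=True)
class MigrationParams:
    """Recession coefficient and the alongshore averaging window.

    If ``bruun_b`` is None it is calibrated as initial_retreat / ref_rise
    (meters per year over meters per year).
    """

    bruun_b: float | None = None
    initial_retreat: float = 15.0       # R_o, m/yr
    ref_rise: float = 0.0045            # historic rise, m/yr
    window_halfwidth: int = 250         # w, rows
    mode: str = "translate"             # or "erode"

    def __post_init__(self) -> None:
        if self.window_halfwidth < 0:
            raise ValueError("window_halfwidth must be non-negative")
        if self.mode not in ("translate", "erode"):
            raise ValueError("mode must be 'translate' or 'erode'")
        if self.bruun_b is not None and self.bruun_b <= 0:
            raise ValueError("bruun_b must be positive")

    @property
    def coefficient(self) -> float:
        if self.bruun_b is not None:
            return self.bruun_b
        return calibrate_bruun(self.initial_retreat, self.ref_rise)


def migration_factor(pc: np.ndarray, subaerial: np.ndarray,
                     halfwidth: int, row: int | None = None):
    """Windowed mean effective cover M_f per alongshore row.

    For row i the window spans rows i-w..i+w (truncated at the grid edge)
    and all columns; M_f is the sum of PC over subaerial cells divided by
    the subaerial cell count, or 0 where the window holds no subaerial cell.
    Returns the full per-row vector, or one value when ``row`` is given.
    """
    pc = np.asarray(pc, dtype=float)
    subaerial = np.asarray(subaerial, dtype=bool)
    num_rows = (pc * subaerial).sum(axis=1)
    den_rows = subaerial.sum(axis=1).astype(float)
    n = num_rows.size
    cnum = np.concatenate(([0.0], np.cumsum(num_rows)))
    cden = np.concatenate(([0.0], np.cumsum(den_rows)))
    idx = np.arange(n)
    lo = np.maximum(idx - halfwidth, 0)
    hi = np.minimum(idx + halfwidth + 1, n)
    num = cnum[hi] - cnum[lo]
    den = cden[hi] - cden[lo]
    mf = np.where(den > 0, num / np.maximum(den, 1.0), 0.0)
    if row is not None:
        return float(mf[row])
    return mf


def row_migration(mf, bruun_b: float, rise_m):
    """Per-row landward migration R_i (m/yr) from the migration factor.

    Exactly zero at M_f >= 0.5; (1 - 2 M_f) B S below; never negative.
    """
    mf = np.asarray(mf, dtype=float)
    r = (1.0 - 2.0 * mf) * bruun_b * rise_m
    r = np.where(mf >= 0.5, 0.0, r)
    return np.maximum(r, 0.0)


def apply_migration(state: IslandState, migration_m: np.ndarray,
                    carry_m: np.ndarray) -> np.ndarray:
    """Translate each row landward by whole cells, in place.

    ``migration_m`` (m) is added to the per-row carry; whole cells are
    applied (floor), the remainder stays in the returned carry.  Vacated
    ocean-side cells become water (H = 0, bare); columns pushed past the
    landward edge are lost.
    """
    grid = state.grid
    total = np.asarray(carry_m, dtype=float) + np.asarray(migration_m,
                                                          dtype=float)
    shifts = np.floor(total / grid.cell_size).astype(int)
    carry = total - shifts * grid.cell_size
    m = grid.n_cols
    for s in np.unique(shifts):
        if s <= 0:
            continue
        rows = np.nonzero(shifts == s)[0]
        s_eff = min(s, m)
        if s_eff < m:
            state.height[rows, : m - s_eff] = state.height[rows, s_eff:]
            state.cover[:, rows, : m - s_eff] = state.cover[:, rows, s_eff:]
        state.height[rows, m - s_eff:] = 0
        state.cover[:, rows, m - s_eff:] = 0.0
    return carry


def apply_erosion(state: IslandState, migration_m: np.ndarray,
                  carry_m: np.ndarray) -> np.ndarray:
    """Erosion-only alternative: drown the easternmost subaerial columns of
    each row instead of translating the profile."""
    grid = state.grid
    total = np.asarray(carry_m, dtype=float) + np.asarray(migration_m,
                                                          dtype=float)
    shifts = np.floor(total / grid.cell_size).astype(int)
    carry = total - shifts * grid.cell_size
    sub = state.subaerial_mask()
    for i in np.nonzero(shifts > 0)[0]:
        cols = np.nonzero(sub[i])[0]
        if cols.size == 0:
            continue
        doomed = cols[-shifts[i]:]
        state.height[i, doomed] = 0
        state.cover[:, i, doomed] = 0.0
    return carry


def annual_marine_step(state: IslandState, params: MigrationParams,
                       scenario: SLRScenario, year: float,
                       carry_m: np.ndarray, pc: np.ndarray) -> np.ndarray:
    """One yearly marine update in place: raise sea level by S(year), then
    migrate every row by its vegetation-adjusted recession.  Returns the
    updated per-row carry."""
    rise_cm = slr_increment(scenario, year)
    state.sea_level_offset += rise_cm / 100.0
    sub = state.subaerial_mask()
    mf = migration_factor(pc, sub, params.window_halfwidth)
    r = row_migration(mf, params.coefficient, rise_cm / 100.0)
    if params.mode == "translate":
        return apply_migration(state, r, carry_m)
    return apply_erosion(state, r, carry_m)
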
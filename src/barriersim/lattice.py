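"""Grid world for the slab-lattice barrier island.

The landscape is a regular lattice of square cells of edge ``L`` (meters).
Elevation is stored as an integer count of sediment slabs, each of thickness
``delta`` (meters), measured relative to the sea-level datum at the start of
the simulation.  Sea level itself is tracked as a continuous offset in meters
above that datum, so elevation comparisons never re-quantize the slab grid
(annual sea-level increments of ~0.5-2 cm are far below the 10 cm slab).

Conventions fixed here and used throughout the package:

* rows index the alongshore direction (row 0 is the northernmost row);
* columns index the cross-shore direction with the ocean on the high-column
  (eastern) side, so landward migration moves material toward low columns;
* a cell is *subaerial* iff its effective elevation (slab height minus the
  current sea-level offset) is strictly positive -- boundary cells are water;
* the grid boundary is open: slabs transported off-grid leave the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: number of plant species tracked on the lattice
N_SPECIES = 4


class SimulationError(RuntimeError):
    """Raised when a state invariant is violated after a named process step."""


@dataclass(frozen=True)
class GridSpec:
    """Lattice geometry: cell counts, cell edge length and slab thickness."""

    n_rows: int
    n_cols: int
    cell_size: float = 4.0      # L, meters (cell edge = slab footprint edge)
    slab_thickness: float = 0.1  # delta, meters

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValueError("grid must be at least 3x3")
        if self.cell_size <= 0 or self.slab_thickness <= 0:
            raise ValueError("cell_size and slab_thickness must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass
class IslandState:
    """The full mutable world: elevation slabs, species cover, sea level.

    Attributes
    ----------
    grid : GridSpec
    height : (n_rows, n_cols) int array
        Slab counts H(i, j) relative to the start-of-run datum; never negative.
    cover : (4, n_rows, n_cols) float array
        Fractional cover P_k of the four species, each in [0, 1].
    sea_level_offset : float
        Meters of sea level above the datum.
    year : float
        Current simulation date (calendar year plus fraction).
    """

    grid: GridSpec
    height: np.ndarray
    cover: np.ndarray
    sea_level_offset: float = 0.0
    year: float = 0.0

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height)
        if self.height.shape != self.grid.shape:
            raise ValueError("height shape does not match grid")
        if not np.issubdtype(self.height.dtype, np.integer):
            if not np.all(self.height == np.round(self.height)):
                raise ValueError("height must hold integer slab counts")
            self.height = self.height.astype(np.int64)
        self.cover = np.asarray(self.cover, dtype=float)
        if self.cover.shape != (N_SPECIES, *self.grid.shape):
            raise ValueError("cover must have shape (4, n_rows, n_cols)")

    # -- elevation semantics -------------------------------------------------

    def effective_elevation(self) -> np.ndarray:
        """Meters above *current* sea level, H * delta - sea_level_offset."""
        return self.height * self.grid.slab_thickness - self.sea_level_offset

    def subaerial_mask(self) -> np.ndarray:
        """Boolean grid, true exactly where effective elevation > 0."""
        return self.effective_elevation() > 0.0

    def copy(self) -> "IslandState":
        return IslandState(
            grid=self.grid,
            height=self.height.copy(),
            cover=self.cover.copy(),
            sea_level_offset=self.sea_level_offset,
            year=self.year,
        )


def effective_elevation(state: IslandState, cell: tuple[int, int] | None = None):
    """Effective elevation (m above current sea level) of one cell or all.

    ``cell`` indices outside the grid raise ``IndexError``.
    """
    elev = state.effective_elevation()
    if cell is None:
        return elev
    r, c = cell
    if not (0 <= r < state.grid.n_rows and 0 <= c < state.grid.n_cols):
        raise IndexError(f"cell {cell} outside {state.grid.shape} grid")
    return float(elev[r, c])


def subaerial_mask(state: IslandState) -> np.ndarray:
    return state.subaerial_mask()


def check_state(state: IslandState, species, cover_cap_total: float,
                context: str = "") -> None:
    """Validate all IslandState invariants; raise SimulationError naming
    the offending process step otherwise."""
    where = f" after step '{context}'" if context else ""
    if np.any(state.height < 0):
        raise SimulationError(f"negative slab count{where}")
    tol = 1e-9
    if np.any(state.cover < -tol):
        raise SimulationError(f"negative plant cover{where}")
    for k, sp in enumerate(species):
        if np.any(state.cover[k] > sp.cover_max + tol):
            raise SimulationError(
                f"cover of {sp.name} exceeds its cap {sp.cover_max}{where}")
    if np.any(state.cover.sum(axis=0) > cover_cap_total + tol):
        raise SimulationError(
            f"total cover exceeds global cap {cover_cap_total}{where}")
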
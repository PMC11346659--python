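"""Shoreline extraction and the mean-annual-regression metrics.

The shoreline of a transect (an alongshore row) is the easternmost
subaerial cell of that row, expressed in meters (column index times the
cell size); rows with no subaerial cell are flagged absent (NaN) and
excluded from every average.  The island splits into an upper and a lower
half at the midpoint row between its northern and southern subaerial tips
(the midpoint row belongs to the upper half).  Mean annual regression over
a year range is the average, over transects present at both epochs, of the
westward (landward) shoreline displacement divided by the elapsed years.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import IslandState


def shoreline_positions(state: IslandState) -> np.ndarray:
    """Eastern (ocean-side) shoreline position of every row, in meters;
    NaN where the row holds no subaerial cell."""
    sub = state.subaerial_mask()
    n, m = state.grid.shape
    has = sub.any(axis=1)
    # index of the last True per row
    last = m - 1 - np.argmax(sub[:, ::-1], axis=1)
    pos = np.where(has, last * state.grid.cell_size, np.nan)
    return pos


def shoreline_position(state: IslandState, row: int) -> float:
    """Shoreline position (m) of one row; NaN when absent."""
    return float(shoreline_positions(state)[row])


def split_rows(state: IslandState) -> tuple[np.ndarray, np.ndarray]:
    """(upper, lower) row indices split at the midpoint between the island
    tips; the midpoint row is assigned to the upper half."""
    has = state.subaerial_mask().any(axis=1)
    idx = np.nonzero(has)[0]
    if idx.size == 0:
        raise ValueError("island is empty: no subaerial cells")
    first, last = idx[0], idx[-1]
    mid = (first + last) // 2
    rows = np.arange(first, last + 1)
    return rows[rows <= mid], rows[rows > mid]


def mean_annual_regression(pos0: np.ndarray, pos1: np.ndarray,
                           t0: float, t1: float,
                           rows: np.ndarray | None = None) -> float:
    """Average westward shoreline movement (m/yr) between two epochs.

    Only transects with a defined shoreline at both epochs enter the
    average; ``rows`` restricts to a subset (e.g. one island half).
    Westward (landward) movement is positive.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    pos0 = np.asarray(pos0, dtype=float)
    pos1 = np.asarray(pos1, dtype=float)
    if rows is not None:
        pos0, pos1 = pos0[rows], pos1[rows]
    ok = np.isfinite(pos0) & np.isfinite(pos1)
    if not ok.any():
        raise ValueError("no transects present at both epochs")
    return float(np.mean(pos0[ok] - pos1[ok]) / (t1 - t0))


@dataclass
class MigrationReport:
    """Annual per-transect shoreline record plus half-island split.

    ``years`` has length T; ``positions`` is (T, n_rows) in meters with NaN
    for absent transects; ``upper_rows``/``lower_rows`` are the transect
    sets of the two island halves, fixed from the initial state.
    """

    years: np.ndarray
    positions: np.ndarray
    upper_rows: np.ndarray
    lower_rows: np.ndarray

    @classmethod
    def from_positions(cls, years: np.ndarray, positions: np.ndarray,
                       initial: IslandState) -> "MigrationReport":
        upper, lower = split_rows(initial)
        return cls(years=np.asarray(years), positions=np.asarray(positions),
                   upper_rows=upper, lower_rows=lower)

    def _epoch(self, rel_year: float) -> int:
        i = int(np.argmin(np.abs(self.years - (self.years[0] + rel_year))))
        return i

    def regression(self, start: float = 0, end: float | None = None,
                   half: str = "all") -> float:
        """Mean annual regression (m/yr) over a relative year range for
        'all', 'upper' or 'lower' transects."""
        if end is None:
            end = float(self.years[-1] - self.years[0])
        i0, i1 = self._epoch(start), self._epoch(end)
        rows = {"all": None, "upper": self.upper_rows,
                "lower": self.lower_rows}[half]
        return mean_annual_regression(self.positions[i0], self.positions[i1],
                                      self.years[i0], self.years[i1], rows)

    def summary(self, ranges: tuple[tuple[float, float], ...] | None = None,
                ) -> pd.DataFrame:
        """Regression table (m/yr): halves x year ranges, mirroring the
        0-15 / 15-30 / 0-30 reporting grid."""
        span = float(self.years[-1] - self.years[0])
        if ranges is None:
            half_span = span / 2
            ranges = ((0.0, half_span), (half_span, span), (0.0, span))
        records = []
        for half in ("upper", "lower", "all"):
            for (a, b) in ranges:
                records.append({
                    "half": half,
                    "years": f"{a:g}-{b:g}",
                    "regression_m_per_yr": self.regression(a, b, half),
                })
        return pd.DataFrame.from_records(records)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.positions, index=self.years)
        df.index.name = "year"
        df.to_csv(path)


def export_contours(snapshots: dict[int, IslandState], out_dir: str | Path,
                    levels: tuple[float, ...] = (0.0),
                    make_figure: bool = True) -> list[Path]:
    """Write shoreline (and other level) contours of each snapshot as
    delimited vertex lists, plus one overlay figure of the 0-m outlines.

    Vertices are in meters (row_m northing from the top row, col_m easting).
    Returns the paths written.
    """
    from skimage import measure

    if isinstance(levels, (int, float)):
        levels = (float(levels),)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    outlines: dict[int, list[np.ndarray]] = {}
    for year, state in sorted(snapshots.items()):
        L = state.grid.cell_size
        elev = state.effective_elevation()
        rows = []
        outlines[year] = []
        for level in levels:
            contours = measure.find_contours(elev, level)
            for ci, verts in enumerate(contours):
                if level == 0.0:
                    outlines[year].append(verts * L)
                for vi, (r, c) in enumerate(verts):
                    rows.append({"level_m": level, "contour": ci,
                                 "vertex": vi, "row_m": r * L, "col_m": c * L})
        path = out_dir / f"contours_year{year}.csv"
        pd.DataFrame(rows, columns=["level_m", "contour", "vertex",
                                    "row_m", "col_m"]).to_csv(path,
                                                              index=False)
        written.append(path)
    if make_figure and outlines:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 8))
        for year, segs in outlines.items():
            color = None
            for seg in segs:
                (line,) = ax.plot(seg[:, 1], seg[:, 0], color=color,
                                  label=f"year {year}" if color is None
                                  else None)
                color = line.get_color()
        ax.invert_yaxis()
        ax.set_xlabel("easting (m)")
        ax.set_ylabel("northing from top row (m)")
        ax.legend(loc="upper right", fontsize=8)
        fig_path = out_dir / "contours.png"
        fig.savefig(fig_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(fig_path)
    return written
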
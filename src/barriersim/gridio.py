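"""Plain-text raster and wind-table I/O.

Rasters use the ESRI ASCII grid dialect (``ncols``/``nrows``/``xllcorner``/
``yllcorner``/``cellsize``/``NODATA_value`` header followed by the grid,
row 1 = northernmost).  Elevation grids hold integer slab counts; cover
grids hold fractions at full precision.  Wind tables are CSV with columns
``timestamp``, ``speed_mps``, ``direction``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import GridSpec, IslandState, N_SPECIES
from .aeolian import WindRecord

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "NODATA_value")


def write_ascii_grid(path: str | Path, grid: np.ndarray, cellsize: float,
                     nodata: float = -9999, xll: float = 0.0,
                     yll: float = 0.0) -> None:
    grid = np.asarray(grid)
    is_int = np.issubdtype(grid.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {xll:g}\n")
        fh.write(f"yllcorner {yll:g}\n")
        fh.write(f"cellsize {cellsize:g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        fmt = "%d" if is_int else "%.10g"
        np.savetxt(fh, grid, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Returns (grid, header); NODATA cells become NaN (float grids) or
    stay at the NODATA value (integer grids)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(len(_HEADER_KEYS)):
            line = fh.readline()
            key, _, value = line.partition(" ")
            if key.strip().lower() not in {k.lower() for k in _HEADER_KEYS}:
                fh.seek(pos)
                break
            header[key.strip()] = float(value)
            pos = fh.tell()
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("NODATA_value")
    if nodata is not None and np.any(data == nodata):
        if np.all(data == np.round(data)):
            pass  # keep integer semantics; caller interprets NODATA
        else:
            data = np.where(data == nodata, np.nan, data)
    if np.all(data == np.round(data)) and np.all(np.isfinite(data)):
        data = data.astype(np.int64)
    return data, header


def save_state(state: IslandState, out_dir: str | Path,
               prefix: str = "") -> list[Path]:
    """Write elevation plus the four cover rasters and a metadata sidecar
    (sea-level offset, date, slab thickness); returns paths."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L = state.grid.cell_size
    paths = []
    p = out_dir / f"{prefix}elevation.asc"
    write_ascii_grid(p, state.height, L)
    paths.append(p)
    for k in range(N_SPECIES):
        p = out_dir / f"{prefix}cover_{k + 1}.asc"
        write_ascii_grid(p, state.cover[k], L)
        paths.append(p)
    meta = out_dir / f"{prefix}meta.json"
    meta.write_text(json.dumps({
        "sea_level_offset": state.sea_level_offset,
        "year": state.year,
        "slab_thickness": state.grid.slab_thickness,
    }))
    paths.append(meta)
    return paths


def load_state(in_dir: str | Path, grid: GridSpec | None = None,
               prefix: str = "", sea_level_offset: float | None = None,
               year: float | None = None) -> IslandState:
    """Read a saved state; the metadata sidecar supplies offset/date unless
    overridden explicitly."""
    import json

    in_dir = Path(in_dir)
    height, header = read_ascii_grid(in_dir / f"{prefix}elevation.asc")
    meta_path = in_dir / f"{prefix}meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if grid is None:
        grid = GridSpec(height.shape[0], height.shape[1],
                        cell_size=header.get("cellsize", 4.0),
                        slab_thickness=meta.get("slab_thickness", 0.1))
    cover = np.zeros((N_SPECIES, *grid.shape))
    for k in range(N_SPECIES):
        path = in_dir / f"{prefix}cover_{k + 1}.asc"
        if path.exists():
            cover[k], _ = read_ascii_grid(path)
    if sea_level_offset is None:
        sea_level_offset = meta.get("sea_level_offset", 0.0)
    if year is None:
        year = meta.get("year", 0.0)
    return IslandState(grid=grid, height=height, cover=cover,
                       sea_level_offset=sea_level_offset, year=year)


def write_wind_table(path: str | Path, records: list[WindRecord]) -> None:
    df = pd.DataFrame({
        "timestamp": np.arange(len(records)),
        "speed_mps": [r.speed for r in records],
        "direction": [r.direction for r in records],
    })
    df.to_csv(path, index=False)


def read_wind_table(path: str | Path) -> list[WindRecord]:
    df = pd.read_csv(path)
    return [WindRecord(float(s), str(d))
            for s, d in zip(df["speed_mps"], df["direction"])]
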
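"""Shoreline metrics, regression summaries, raster round-trips, contour
export and the CLI surface."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from barriersim import (GridSpec, IslandState, MigrationReport,
                        apply_migration, export_contours,
                        mean_annual_regression, shoreline_position,
                        shoreline_positions, split_rows)
from barriersim.gridio import (read_ascii_grid, read_wind_table, save_state,
                               load_state, write_ascii_grid,
                               write_wind_table)
from barriersim.aeolian import WindRecord
from barriersim.cli import main as cli_main


def _strip_island(n_rows=8, last_col=50, n_cols=60):
    grid = GridSpec(n_rows, n_cols)
    h = np.zeros(grid.shape, dtype=np.int64)
    h[:, 10:last_col + 1] = 5
    return IslandState(grid=grid, height=h, cover=np.zeros((4, *grid.shape)))


def test_shoreline_position_is_easternmost_subaerial_times_cellsize():
    state = _strip_island(last_col=50)
    assert shoreline_position(state, 3) == 200.0


def test_all_water_row_is_flagged_absent():
    state = _strip_island()
    state.height[2] = 0
    assert np.isnan(shoreline_position(state, 2))
    assert np.isfinite(shoreline_positions(state)[[0, 1, 3]]).all()


def test_shoreline_follows_migration():
    state = _strip_island()
    before = shoreline_positions(state)
    apply_migration(state, np.full(8, 8.0), np.zeros(8))
    after = shoreline_positions(state)
    np.testing.assert_allclose(before - after, 8.0)


def test_split_rows_midpoint():
    grid = GridSpec(130, 20)
    h = np.zeros(grid.shape, dtype=np.int64)
    h[10:111, 5:15] = 3  # tips at rows 10 and 110
    state = IslandState(grid=grid, height=h, cover=np.zeros((4, *grid.shape)))
    upper, lower = split_rows(state)
    assert upper[0] == 10 and upper[-1] == 60   # midpoint joins the upper half
    assert lower[0] == 61 and lower[-1] == 110


def test_split_rows_single_row_island():
    grid = GridSpec(10, 10)
    h = np.zeros(grid.shape, dtype=np.int64)
    h[4, 3:7] = 2
    state = IslandState(grid=grid, height=h, cover=np.zeros((4, *grid.shape)))
    upper, lower = split_rows(state)
    assert list(upper) == [4] and len(lower) == 0


def test_split_rows_symmetric_island_has_equal_halves():
    state = _strip_island(n_rows=8)
    upper, lower = split_rows(state)
    assert len(upper) == len(lower)


def test_split_rows_empty_island_raises(flat_state):
    with pytest.raises(ValueError):
        split_rows(flat_state)


def test_mean_annual_regression_values():
    pos0 = np.full(10, 400.0)
    assert mean_annual_regression(pos0, pos0, 0, 10) == 0.0
    assert mean_annual_regression(pos0, pos0 - 40.0, 0, 10) == pytest.approx(
        4.0)
    mixed = pos0 - np.where(np.arange(10) < 5, 8.0, 0.0)
    assert mean_annual_regression(pos0, mixed, 0, 1) == pytest.approx(4.0)


def test_mean_annual_regression_excludes_absent_rows():
    pos0 = np.array([400.0, np.nan, 400.0])
    pos1 = np.array([360.0, 100.0, np.nan])
    assert mean_annual_regression(pos0, pos1, 0, 10) == pytest.approx(4.0)


def test_mean_annual_regression_requires_presence():
    with pytest.raises(ValueError):
        mean_annual_regression(np.array([np.nan]), np.array([1.0]), 0, 1)
    with pytest.raises(ValueError):
        mean_annual_regression(np.array([1.0]), np.array([2.0]), 1, 1)


def test_report_summary_table():
    years = np.arange(2020, 2031)
    pos = np.tile(np.linspace(400, 360, 11)[:, None], (1, 6))
    state = _strip_island(n_rows=6)
    report = MigrationReport.from_positions(years, pos, state)
    df = report.summary(((0, 5), (5, 10), (0, 10)))
    assert len(df) == 9
    np.testing.assert_allclose(df["regression_m_per_yr"], 4.0)


# -- raster I/O --------------------------------------------------------------

def test_ascii_grid_roundtrip_integer(tmp_path):
    grid = np.arange(12, dtype=np.int64).reshape(3, 4)
    path = tmp_path / "h.asc"
    write_ascii_grid(path, grid, cellsize=4.0)
    back, header = read_ascii_grid(path)
    np.testing.assert_array_equal(back, grid)
    assert header["cellsize"] == 4.0
    assert np.issubdtype(back.dtype, np.integer)


def test_ascii_grid_roundtrip_float(tmp_path):
    rng = np.random.default_rng(0)
    grid = rng.uniform(0, 0.8, (5, 7))
    path = tmp_path / "c.asc"
    write_ascii_grid(path, grid, cellsize=4.0)
    back, _ = read_ascii_grid(path)
    np.testing.assert_allclose(back, grid, rtol=1e-9)


def test_state_roundtrip(tmp_path, tiny_island):
    save_state(tiny_island, tmp_path)
    back = load_state(tmp_path, sea_level_offset=tiny_island.sea_level_offset)
    np.testing.assert_array_equal(back.height, tiny_island.height)
    np.testing.assert_allclose(back.cover, tiny_island.cover, rtol=1e-9)
    assert back.grid.cell_size == tiny_island.grid.cell_size


def test_wind_table_roundtrip(tmp_path):
    records = [WindRecord(7.5, "E"), WindRecord(12.0, "NW")]
    path = tmp_path / "wind.csv"
    write_wind_table(path, records)
    assert read_wind_table(path) == records


# -- contours ----------------------------------------------------------------

def test_rectangular_island_rectangular_contour(tmp_path):
    state = _strip_island()
    paths = export_contours({0: state}, tmp_path, make_figure=False)
    df = pd.read_csv(paths[0])
    assert len(df) > 0
    # the 0-contour hugs the strip footprint
    assert df["col_m"].min() >= 9 * 4 - 4 and df["col_m"].max() <= 51 * 4 + 4


def test_empty_state_empty_contours(tmp_path, flat_state):
    paths = export_contours({0: flat_state}, tmp_path, make_figure=False)
    assert pd.read_csv(paths[0]).empty


def test_contours_shift_with_migration(tmp_path):
    s0 = _strip_island()
    s1 = s0.copy()
    apply_migration(s1, np.full(8, 4.0), np.zeros(8))
    paths = export_contours({0: s0, 1: s1}, tmp_path, make_figure=False)
    a = pd.read_csv(paths[0])
    b = pd.read_csv(paths[1])
    assert b["col_m"].max() == pytest.approx(a["col_m"].max() - 4.0)


# -- CLI ---------------------------------------------------------------------

def test_cli_simulate_on_tiny_island(tmp_path, tiny_template):
    """End-to-end CLI run on a reduced island writes snapshots + summary."""
    from barriersim import config as _config
    from barriersim.gridio import save_state as _save

    cfg = _config.desk_config(
        seed=5, grid=tiny_template.grid, start_year=2020, end_year=2022,
        migration=_config.MigrationParams(window_halfwidth=6),
        snapshot_years=(0, 2))
    cfg_path = tmp_path / "cfg.yaml"
    _config.to_yaml(cfg, cfg_path)
    from barriersim import make_island_with_vegetation
    init_dir = tmp_path / "init"
    state = make_island_with_vegetation(tiny_template)
    _save(state, init_dir)

    out = tmp_path / "run"
    runner = CliRunner()
    result = runner.invoke(cli_main, [
        "simulate", "--config", str(cfg_path), "--initial", str(init_dir),
        "--out", str(out)])
    assert result.exit_code == 0, result.output
    assert (out / "summary.csv").exists()
    assert (out / "positions.csv").exists()
    assert (out / "year0_elevation.asc").exists()
    df = pd.read_csv(out / "summary.csv")
    assert np.isfinite(df["regression_m_per_yr"]).all()


def test_cli_make_island(tmp_path):
    runner = CliRunner()
    result = runner.invoke(cli_main, [
        "make-island", "--out", str(tmp_path / "isle"), "--seed", "2",
        "--wind-steps", "10"])
    assert result.exit_code == 0, result.output
    assert (tmp_path / "isle" / "elevation.asc").exists()
    assert (tmp_path / "isle" / "wind.csv").exists()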
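"""Sea-level curves, the Bruun-type recession coefficient, the windowed
migration factor, per-row migration and its lattice realization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barriersim import (BruunGeometry, GridSpec, IslandState, MigrationParams,
                        SCENARIOS, SLRScenario, apply_migration,
                        bruun_coefficient, calibrate_bruun, migration_factor,
                        row_migration, sea_level, slr_increment)


# -- sea-level curve ---------------------------------------------------------

def test_anchor_year_level_shared_by_all_scenarios():
    for scn in SCENARIOS.values():
        assert sea_level(scn, 1992) == pytest.approx(3.6)


def test_datum_year_is_zero():
    assert sea_level(SCENARIOS["historic"], 1984) == pytest.approx(0.0)


@pytest.mark.parametrize("name, year, expected", [
    ("historic", 2050, 0.45 * 58 + 3.6),
    ("highest", 2050, 0.45 * 58 + 0.0157 * 58**2 + 3.6),
    ("low", 2050, 0.45 * 58 + 0.0043 * 58**2 + 3.6),
])
def test_sea_level_2050(name, year, expected):
    assert sea_level(SCENARIOS[name], year) == pytest.approx(expected)


def test_sea_level_rejects_pre_datum_year():
    with pytest.raises(ValueError):
        sea_level(SCENARIOS["historic"], 1983)


def test_increment_constant_for_linear_scenario():
    for year in (1993, 2000, 2049):
        assert slr_increment(SCENARIOS["historic"], year) == pytest.approx(
            0.45)


def test_increment_accelerating_scenario():
    # 0.45 + 0.0157*(29^2 - 28^2)
    assert slr_increment(SCENARIOS["highest"], 2021) == pytest.approx(1.3449)


def test_increment_zero_for_static_sea():
    scn = SLRScenario("static", a=0.0, b=0.0, c=3.6)
    assert slr_increment(scn, 2030) == 0.0


def test_curve_monotone_and_scenarios_ordered():
    years = np.arange(1984, 2051)
    ordered = ["historic", "low", "high", "highest"]
    curves = {n: np.array([sea_level(SCENARIOS[n], y) for y in years])
              for n in ordered}
    for n in ordered:
        assert (np.diff(curves[n]) >= 0).all()
    for lo, hi in zip(ordered, ordered[1:]):
        assert (curves[lo] <= curves[hi] + 1e-12).all()


# -- recession coefficient ---------------------------------------------------

def test_bruun_coefficient_from_geometry():
    geom = BruunGeometry(width=100, shore_len_ocean=100, shore_len_lagoon=100,
                         berm_ocean=3, depth_ocean=1, berm_lagoon=0.5,
                         depth_lagoon=0.5)
    assert bruun_coefficient(geom) == pytest.approx(300 / 3)


def test_bruun_coefficient_zero_numerator():
    geom = BruunGeometry(width=0, shore_len_ocean=0, shore_len_lagoon=0,
                         berm_ocean=2, depth_ocean=2, berm_lagoon=0,
                         depth_lagoon=0)
    assert bruun_coefficient(geom) == 0.0


def test_bruun_coefficient_degenerate_denominator():
    geom = BruunGeometry(width=10, shore_len_ocean=10, shore_len_lagoon=10,
                         berm_ocean=1, depth_ocean=1, berm_lagoon=1,
                         depth_lagoon=1)
    with pytest.raises(ValueError):
        bruun_coefficient(geom)


def test_calibrated_coefficient():
    """15 m/yr of observed retreat over the 0.45 cm/yr historic rise."""
    assert calibrate_bruun(15.0, 0.0045) == pytest.approx(3333.33, rel=1e-4)
    assert MigrationParams().coefficient == pytest.approx(3333.33, rel=1e-4)


# -- migration factor --------------------------------------------------------

def _state_with(pc_value, grid=None):
    grid = grid or GridSpec(10, 8)
    h = np.full(grid.shape, 5, dtype=np.int64)
    return grid, h


def test_migration_factor_bare():
    pc = np.zeros((10, 8))
    sub = np.ones((10, 8), dtype=bool)
    assert migration_factor(pc, sub, 2, row=4) == 0.0


def test_migration_factor_uniform_cover():
    pc = np.full((10, 8), 0.4)
    sub = np.ones((10, 8), dtype=bool)
    np.testing.assert_allclose(migration_factor(pc, sub, 3), 0.4)


def test_migration_factor_mean_over_subaerial_only():
    """3x4 window with 6 subaerial cells of PC {.2,.2,.8,.8,.5,.5}: 0.5."""
    pc = np.zeros((3, 4))
    sub = np.zeros((3, 4), dtype=bool)
    values = [0.2, 0.2, 0.8, 0.8, 0.5, 0.5]
    cells = [(0, 0), (0, 3), (1, 1), (1, 2), (2, 0), (2, 2)]
    for (r, c), v in zip(cells, values):
        sub[r, c] = True
        pc[r, c] = v
    assert migration_factor(pc, sub, 1, row=1) == pytest.approx(0.5)


def test_migration_factor_window_truncates_at_edges():
    pc = np.zeros((6, 2))
    pc[0] = 1.0
    sub = np.ones((6, 2), dtype=bool)
    mf = migration_factor(pc, sub, 1)
    assert mf[0] == pytest.approx(0.5)   # rows 0-1 only
    assert mf[1] == pytest.approx(1 / 3)  # rows 0-2
    assert mf[5] == pytest.approx(0.0)


def test_migration_factor_empty_window_is_zero():
    pc = np.full((4, 4), 0.7)
    sub = np.zeros((4, 4), dtype=bool)
    assert (migration_factor(pc, sub, 1) == 0).all()


# -- per-row migration -------------------------------------------------------

@pytest.mark.parametrize("mf, factor", [
    (0.0, 1.0),       # bare: full Bruun recession
    (0.25, 0.5),      # (1 - 2*0.25)
    (0.5, 0.0),       # shutoff begins exactly at half cover
    (0.6, 0.0),
    (1.0, 0.0),
])
def test_row_migration_adjustment(mf, factor):
    b_s = 15.0
    assert row_migration(mf, 3333.3, 0.0045) == pytest.approx(
        factor * 3333.3 * 0.0045)
    assert row_migration(np.array([mf]), 1000.0, 0.015)[0] == pytest.approx(
        factor * 15.0)


def test_row_migration_exact_zero_at_half_cover():
    assert row_migration(0.5, 3333.3, 0.0045) == 0.0


@settings(deadline=None, derandomize=True)
@given(st.floats(0, 1), st.floats(0, 1))
def test_row_migration_monotone_and_nonnegative(m1, m2):
    r1, r2 = row_migration(m1, 3333.3, 0.0045), row_migration(m2, 3333.3,
                                                              0.0045)
    assert r1 >= 0 and r2 >= 0
    if m1 <= m2:
        assert r1 >= r2 - 1e-9


def test_row_migration_continuous_at_half():
    eps = 1e-9
    below = row_migration(0.5 - eps, 3333.3, 0.0045)
    assert below == pytest.approx(0.0, abs=1e-4)


# -- lattice realization -----------------------------------------------------

def _island_strip():
    grid = GridSpec(5, 12)
    h = np.zeros(grid.shape, dtype=np.int64)
    h[:, 4:10] = 10
    c = np.zeros((4, *grid.shape))
    c[0, :, 5:8] = 0.5
    return IslandState(grid=grid, height=h, cover=c)


def test_apply_migration_zero_is_identity():
    state = _island_strip()
    h0, c0 = state.height.copy(), state.cover.copy()
    carry = apply_migration(state, np.zeros(5), np.zeros(5))
    np.testing.assert_array_equal(state.height, h0)
    np.testing.assert_array_equal(state.cover, c0)
    np.testing.assert_allclose(carry, 0.0)


def test_apply_migration_floor_and_carry():
    """6 m/yr on 4 m cells: one cell now, 2 m carried."""
    state = _island_strip()
    carry = apply_migration(state, np.full(5, 6.0), np.zeros(5))
    np.testing.assert_allclose(carry, 2.0)
    assert (state.height[:, 3:9] == 10).all()
    assert (state.height[:, 9:] == 0).all()
    # vegetation translates with the substrate
    assert (state.cover[0, :, 4:7] == 0.5).all()


def test_apply_migration_two_years_resolve_carry():
    """Two years at 6 m/yr equal 3 whole cells with zero carry."""
    state = _island_strip()
    carry = apply_migration(state, np.full(5, 6.0), np.zeros(5))
    carry = apply_migration(state, np.full(5, 6.0), carry)
    np.testing.assert_allclose(carry, 0.0)
    assert (state.height[:, 1:7] == 10).all()
    assert (state.height[:, 7:] == 0).all()


def test_apply_migration_uniform_rows_keep_straight_shoreline():
    state = _island_strip()
    apply_migration(state, np.full(5, 8.0), np.zeros(5))
    last = [np.nonzero(state.height[i])[0][-1] for i in range(5)]
    assert len(set(last)) == 1
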
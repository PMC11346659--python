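"""Angle-of-repose relaxation of over-steep slopes.

The slope between a cell and each of its four von Neumann neighbours is

    theta' = arctan(delta * (H_center - H_neighbor) / L),

the physical angle of the height difference over one cell width.  Whenever
theta' reaches the critical angle of repose theta_o the cell is in
violation, and avalanches one slab onto its steepest violating neighbour
with probability

    rho_av = min(1, (theta'/theta_o) * (1 - PC)),

where PC is the effective cover of the avalanching (source) cell.  With the
default theta_o = pi/6, delta = 0.1 m and L = 4 m the smallest violating
height difference is 24 slabs.

Relaxation runs in synchronous passes decided on the pre-pass surface:
every violating cell independently draws its move, ties for the steepest
neighbour are broken uniformly at random, and passes repeat until no pair
violates theta_o or a pass cap is hit (with vegetation present termination
is only probabilistic, so a cap is required; hitting it logs a warning).
Slabs only relocate between in-grid neighbours, so the total slab count is
conserved exactly and the maximum elevation never increases.  With PC = 0
everywhere, rho_av >= 1 for every violation and each pass strictly lowers
the sum of squared heights, so relaxation terminates violation-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import GridSpec, IslandState

#: neighbour offsets in the fixed order north, south, west, east
_NBR = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class ReposeParams:
    """Critical angle of repose (radians) and the relaxation pass cap."""

    critical_angle: float = math.pi / 6
    max_passes: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.critical_angle < math.pi / 2):
            raise ValueError("critical_angle must lie in (0, pi/2)")
        if self.max_passes < 1:
            raise ValueError("max_passes must be at least 1")


def repose_angle(h_center, h_neighbor, grid: GridSpec):
    """Slope angle (radians) between two neighbouring slab columns."""
    dh = (np.asarray(h_center, dtype=float) - np.asarray(h_neighbor, dtype=float))
    return np.arctan(grid.slab_thickness * dh / grid.cell_size)


def avalanche_probability(theta, theta_o: float, pc):
    """rho_av = min(1, (theta'/theta_o) * (1 - PC))."""
    return np.minimum(1.0, (np.asarray(theta, dtype=float) / theta_o)
                      * (1.0 - np.asarray(pc, dtype=float)))


def _neighbor_drops(height: np.ndarray) -> np.ndarray:
    """(4, n, m) height drops to each von Neumann neighbour; out-of-grid
    neighbours mirror the centre (drop 0), so edges never avalanche off-grid."""
    hp = np.pad(height, 1, mode="edge")
    n, m = height.shape
    drops = np.empty((4, n, m), dtype=float)
    for a, (dr, dc) in enumerate(_NBR):
        drops[a] = height - hp[1 + dr: 1 + dr + n, 1 + dc: 1 + dc + m]
    return drops


def relax(state: IslandState, pc: np.ndarray, params: ReposeParams,
          rng: np.random.Generator, log=None) -> tuple[int, int]:
    """Relax the surface in place; returns (passes run, slabs moved)."""
    grid = state.grid
    tan_thr = math.tan(params.critical_angle)
    # smallest violating slab drop: delta*dH/L >= tan(theta_o)
    dh_thr = grid.cell_size * tan_thr / grid.slab_thickness
    moved_total = 0
    passes = 0
    for passes in range(1, params.max_passes + 1):
        drops = _neighbor_drops(state.height)
        violating = drops >= dh_thr - 1e-12
        viol_any = violating.any(axis=0)
        if not viol_any.any():
            passes -= 1
            break
        steep = drops.max(axis=0)
        theta = np.arctan(grid.slab_thickness * steep / grid.cell_size)
        rho = avalanche_probability(theta, params.critical_angle, pc)
        move = viol_any & (rng.random(grid.shape) < rho)
        if not move.any():
            continue
        # steepest violating neighbour, ties broken uniformly at random
        score = np.where(violating, drops + rng.random(drops.shape), -np.inf)
        choice = score.argmax(axis=0)
        rows, cols = np.nonzero(move)
        sel = choice[rows, cols]
        off = np.array(_NBR)
        dest_r = rows + off[sel, 0]
        dest_c = cols + off[sel, 1]
        state.height[rows, cols] -= 1
        np.add.at(state.height, (dest_r, dest_c), 1)
        moved_total += rows.size
    else:
        if log is not None:
            log.append(f"avalanche pass cap {params.max_passes} reached "
                       "with violations remaining")
    return passes, moved_total


__all__ = ["ReposeParams", "repose_angle", "avalanche_probability", "relax"]
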
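"""Plant dynamics: growth/immigration, crowding, erosion-effective cover,
elevation-range viability, and rare long-distance dispersal of the shrub.

Four species are tracked (indices fixed package-wide):

0. *Ammophila breviligulata* -- dominant dune-building grass, 1-5 m.
1. *Spartina patens* -- moderate dune builder / high-marsh grass, 0.75-3 m.
2. *Spartina alterniflora* -- low-marsh grass, -0.5-1 m.
3. *Morella cerifera* -- evergreen shrub standing in for all woody
   vegetation; 1.5 m and up, no upper bound.

Each species has an elevation band where it is viable, a per-species cover
cap, an erosion coefficient weighting its ability to pin sediment, and an
annual growth-rate band [g, G] from which a per-cell rate is drawn uniformly
every year.  Cover change in a year is the drawn rate times the total cover
in the 3x3 Moore neighbourhood (the cell itself included), i.e. growth plus
immigration from neighbours; neighbourhoods truncate at the grid edge.

Crowding favours the shrub: when total cover exceeds the global cap M, only
the grasses are trimmed, evenly among those present; the shrub keeps its
(cap-limited) cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .lattice import IslandState, N_SPECIES

#: index of the woody species (Morella) in every cover array
WOODY = 3
_GRASSES = (0, 1, 2)


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species constants.

    elev_min/elev_max : viable elevation band in meters relative to current
        sea level (``math.inf`` for an unbounded top).
    erosion_coeff : alpha_k in [0, 1], weight of this species in the
        erosion-effective cover.
    cover_max : eta_k, per-species cover cap.
    growth_min/growth_max : [g, G], annual growth-rate band (fraction/yr;
        the lower end may be negative, i.e. die-back years).
    """

    name: str
    elev_min: float
    elev_max: float
    erosion_coeff: float
    cover_max: float
    growth_min: float = -0.0002
    growth_max: float = 0.0008

    def __post_init__(self) -> None:
        if not (self.elev_min < self.elev_max):
            raise ValueError("elev_min must be below elev_max")
        if not (0.0 <= self.erosion_coeff <= 1.0):
            raise ValueError("erosion_coeff must lie in [0, 1]")
        if not (0.0 < self.cover_max <= 1.0):
            raise ValueError("cover_max must lie in (0, 1]")
        if self.growth_min > self.growth_max:
            raise ValueError("growth_min must not exceed growth_max")


#: Field-derived defaults for the four mid-Atlantic species.
DEFAULT_SPECIES: tuple[SpeciesParams, ...] = (
    SpeciesParams("Ammophila breviligulata", 1.0, 5.0, 0.667, 0.80),
    SpeciesParams("Spartina patens", 0.75, 3.0, 0.333, 0.80),
    SpeciesParams("Spartina alterniflora", -0.5, 1.0, 1.0, 0.60),
    SpeciesParams("Morella cerifera", 1.5, math.inf, 1.0, 0.60),
)

#: global total-cover cap M
DEFAULT_TOTAL_COVER_CAP = 0.80

_BOX = np.ones((3, 3))


def grow_step(cover_k: np.ndarray, params: SpeciesParams,
              rng: np.random.Generator | None = None,
              gamma: np.ndarray | float | None = None) -> np.ndarray:
    """One annual growth + immigration update for a single species.

    P <- P + gamma * (3x3 neighbourhood sum of P), clipped to [0, eta_k].
    ``gamma`` is drawn uniformly from [g, G] per cell (one draw per cell per
    year, shared by all nine neighbourhood terms); pass it explicitly to
    pin the draw in tests.
    """
    cover_k = np.asarray(cover_k, dtype=float)
    if gamma is None:
        if rng is None:
            raise ValueError("either rng or gamma must be given")
        gamma = rng.uniform(params.growth_min, params.growth_max,
                            size=cover_k.shape)
    neigh = ndimage.convolve(cover_k, _BOX, mode="constant", cval=0.0)
    return np.clip(cover_k + gamma * neigh, 0.0, params.cover_max)


def crowding_adjust(cover: np.ndarray, total_cap: float,
                    woody_cap: float = DEFAULT_SPECIES[WOODY].cover_max,
                    ) -> np.ndarray:
    """Trim grass cover so that the per-cell total does not exceed the cap.

    The shrub is first clipped to its own cap, then the excess of the total
    over ``total_cap`` is deducted evenly from the grasses present on the
    cell.  A grass driven negative is floored at zero and its shortfall is
    re-spread over the grasses still positive (at most three rounds; a
    residual with no grass left to absorb it is dropped, which can only
    happen if the shrub cap itself exceeds the total cap).

    ``cover`` has species on the leading axis; any trailing shape works
    (single cell = shape (4,)).
    """
    cover = np.asarray(cover, dtype=float).copy()
    cover[WOODY] = np.clip(cover[WOODY], 0.0, woody_cap)
    grasses = cover[list(_GRASSES)]
    deficit = np.maximum(0.0, cover.sum(axis=0) - total_cap)
    for _ in range(len(_GRASSES)):
        if not np.any(deficit > 0):
            break
        positive = grasses > 0
        n_pos = positive.sum(axis=0)
        active = (deficit > 0) & (n_pos > 0)
        share = np.where(active, deficit / np.maximum(n_pos, 1), 0.0)
        grasses = grasses - np.where(positive, share, 0.0)
        deficit = np.where(active, -np.minimum(grasses, 0.0).sum(axis=0), 0.0)
        grasses = np.maximum(grasses, 0.0)
    cover[list(_GRASSES)] = grasses
    return cover


def effective_cover(cover: np.ndarray, species=DEFAULT_SPECIES) -> np.ndarray:
    """Erosion-effective plant cover PC = sum_k alpha_k P_k, clipped to <= 1.

    PC is the fraction by which all three sediment processes are attenuated;
    the raw weighted sum can exceed 1 with the default caps, so it is clipped
    to keep it a valid probability factor.
    """
    cover = np.asarray(cover, dtype=float)
    alphas = np.array([sp.erosion_coeff for sp in species])
    pc = np.tensordot(alphas, cover, axes=(0, 0))
    return np.clip(pc, 0.0, 1.0)


def viability_update(cover: np.ndarray, elevation: np.ndarray,
                     species=DEFAULT_SPECIES, decay: float = 0.5,
                     floor: float = 1e-4) -> np.ndarray:
    """Annual die-back of cover sitting outside its species' elevation band.

    Cells whose effective elevation lies outside [elev_min, elev_max] have
    that species' cover multiplied by ``decay``; in-band cells are exactly
    preserved; covers below ``floor`` are zeroed.
    """
    cover = np.asarray(cover, dtype=float).copy()
    elevation = np.asarray(elevation, dtype=float)
    for k, sp in enumerate(species):
        out = (elevation < sp.elev_min) | (elevation > sp.elev_max)
        cover[k] = np.where(out, cover[k] * decay, cover[k])
        cover[k][cover[k] < floor] = 0.0
    return cover


def distant_dispersal(cover: np.ndarray, elevation: np.ndarray,
                      subaerial: np.ndarray, rng: np.random.Generator,
                      species=DEFAULT_SPECIES, prob: float = 1e-3,
                      seed_cover: float = 0.01) -> np.ndarray:
    """Bird-mediated long-distance seeding of the woody species.

    Once a year, if the shrub is present anywhere, every subaerial cell at or
    above its minimum viable elevation that currently has zero shrub cover
    independently gains ``seed_cover`` with probability ``prob``.
    """
    cover = np.asarray(cover, dtype=float).copy()
    if not np.any(cover[WOODY] > 0):
        return cover
    eligible = (subaerial & (elevation >= species[WOODY].elev_min)
                & (cover[WOODY] == 0.0))
    hits = eligible & (rng.random(eligible.shape) < prob)
    cover[WOODY][hits] = seed_cover
    return cover


def annual_update(state: IslandState, species, total_cap: float,
                  rng: np.random.Generator, decay: float = 0.5,
                  floor: float = 1e-4, dispersal_prob: float = 1e-3,
                  dispersal_cover: float = 0.01) -> None:
    """Full once-a-year vegetation update, in place.

    Order: growth/immigration per species, woody dispersal, crowding
    adjustment, elevation-band viability.
    """
    for k, sp in enumerate(species):
        state.cover[k] = grow_step(state.cover[k], sp, rng=rng)
    elev = state.effective_elevation()
    state.cover = distant_dispersal(state.cover, elev, state.subaerial_mask(),
                                    rng, species, dispersal_prob,
                                    dispersal_cover)
    state.cover = crowding_adjust(state.cover, total_cap,
                                  species[WOODY].cover_max)
    for k, sp in enumerate(species):
        np.clip(state.cover[k], 0.0, sp.cover_max, out=state.cover[k])
    state.cover = viability_update(state.cover, elev, species, decay, floor)
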
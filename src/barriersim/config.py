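"""Structured simulation configuration and its YAML form.

A :class:`SimulationConfig` collects the grid, the four species parameter
blocks, the sediment-process constants, the sea-level scenario, the
migration window, and the run window/seed.  ``from_yaml``/``to_yaml`` mirror
the dataclass field names, so a config file reads like the parameter tables
it encodes; any omitted key keeps its default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .lattice import GridSpec
from .vegetation import SpeciesParams, DEFAULT_SPECIES, DEFAULT_TOTAL_COVER_CAP
from .avalanche import ReposeParams
from .marine import SLRScenario, SCENARIOS, MigrationParams
from .synthetic import WindClimate


@dataclass(frozen=True)
class SimulationConfig:
    grid: GridSpec = field(default_factory=lambda: GridSpec(728, 678))
    species: tuple[SpeciesParams, ...] = DEFAULT_SPECIES
    total_cover_cap: float = DEFAULT_TOTAL_COVER_CAP
    scenario: SLRScenario = field(
        default_factory=lambda: SCENARIOS["historic"])
    migration: MigrationParams = field(default_factory=MigrationParams)
    repose: ReposeParams = field(default_factory=ReposeParams)
    wind: WindClimate | str = field(default_factory=WindClimate)
    wind_min: float = 6.0
    wind_max: float = 16.0
    events_per_year: int = 26
    start_year: int = 2020
    end_year: int = 2050
    seed: int = 0
    snapshot_years: tuple[int, ...] = (0, 15, 30)   # relative to start
    viability_decay: float = 0.5
    cover_floor: float = 1e-4
    dispersal_prob: float = 1e-3
    dispersal_cover: float = 0.01
    enable_aeolian: bool = True
    enable_vegetation: bool = True
    enable_marine: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.total_cover_cap <= 1.0):
            raise ValueError("total_cover_cap must lie in (0, 1]")
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")
        if self.events_per_year < 0:
            raise ValueError("events_per_year must be non-negative")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year


def desk_config(seed: int = 0, scenario: str | SLRScenario = "historic",
                window_halfwidth: int = 18, **overrides) -> SimulationConfig:
    """Desk-scale default configuration matching the synthetic island
    template (200 x 560 grid, 2020-2050, window half-width scaled to the
    reduced island length)."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    kwargs = dict(
        grid=GridSpec(200, 560),
        scenario=scenario,
        migration=MigrationParams(window_halfwidth=window_halfwidth),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# -- YAML (de)serialisation --------------------------------------------------

def _species_to_dict(sp: SpeciesParams) -> dict:
    d = asdict(sp)
    if math.isinf(d["elev_max"]):
        d["elev_max"] = None
    return d


def _species_from_dict(d: dict) -> SpeciesParams:
    d = dict(d)
    if d.get("elev_max") is None:
        d["elev_max"] = math.inf
    return SpeciesParams(**d)


def to_dict(cfg: SimulationConfig) -> dict:
    d = {
        "grid": asdict(cfg.grid),
        "species": [_species_to_dict(sp) for sp in cfg.species],
        "total_cover_cap": cfg.total_cover_cap,
        "scenario": asdict(cfg.scenario),
        "migration": asdict(cfg.migration),
        "repose": asdict(cfg.repose),
        "wind": (cfg.wind if isinstance(cfg.wind, str)
                 else {"weibull_shape": cfg.wind.weibull_shape,
                       "weibull_scale": cfg.wind.weibull_scale,
                       "direction_probs": list(cfg.wind.direction_probs)}),
    }
    for key in ("wind_min", "wind_max", "events_per_year", "start_year",
                "end_year", "seed", "viability_decay", "cover_floor",
                "dispersal_prob", "dispersal_cover", "enable_aeolian",
                "enable_vegetation", "enable_marine"):
        d[key] = getattr(cfg, key)
    d["snapshot_years"] = list(cfg.snapshot_years)
    return d


def from_dict(d: dict) -> SimulationConfig:
    kwargs = dict(d)
    if "grid" in kwargs:
        kwargs["grid"] = GridSpec(**kwargs["grid"])
    if "species" in kwargs:
        kwargs["species"] = tuple(_species_from_dict(s)
                                  for s in kwargs["species"])
    if "scenario" in kwargs:
        s = kwargs["scenario"]
        kwargs["scenario"] = (SCENARIOS[s] if isinstance(s, str)
                              else SLRScenario(**s))
    if "migration" in kwargs:
        kwargs["migration"] = MigrationParams(**kwargs["migration"])
    if "repose" in kwargs:
        kwargs["repose"] = ReposeParams(**kwargs["repose"])
    if "wind" in kwargs and not isinstance(kwargs["wind"], str):
        w = dict(kwargs["wind"])
        if "direction_probs" in w:
            w["direction_probs"] = tuple(w["direction_probs"])
        kwargs["wind"] = WindClimate(**w)
    if "snapshot_years" in kwargs:
        kwargs["snapshot_years"] = tuple(kwargs["snapshot_years"])
    return SimulationConfig(**kwargs)


def to_yaml(cfg: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(cfg), sort_keys=False))


def from_yaml(path: str | Path) -> SimulationConfig:
    return from_dict(yaml.safe_load(Path(path).read_text()))
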
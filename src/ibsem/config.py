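"""Configuration loading, validation and test-fixture helpers.

The full parameter tree lives in nested dataclasses whose defaults are the
shipped calibration; a YAML file with the same nesting can override any
subset of keys.  ``load_and_validate`` merges overrides onto the defaults,
checks types, key names and value ranges, and reports violations with the
full dotted key path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .demography import RateParams
from .environment import Environment
from .reproduction import EscapeeParams, SpawningParams, StrayingParams


@dataclass
class InitialPopulation:
    """Abundances and mean sizes at the May start of a simulation."""

    n_p0: float = 600_000.0
    n_p1: float = 30_000.0
    n_p2: float = 30_000.0
    n_smolt: float = 0.0
    n_adult: float = 1_000.0
    len_p0_mm: float = 23.0
    len_p1_mm: float = 65.0
    len_p2_mm: float = 100.0
    len_adult_mm: tuple[float, float, float, float] = (140.0, 560.0, 670.0, 800.0)
    len_sd_p0_mm: float = 1.0
    len_sd_parr_mm: float = 8.0
    len_sd_adult_frac: float = 0.05


@dataclass
class SimConfig:
    environment: Environment = field(default_factory=Environment)
    genetics_decay: float = 0.3
    wild_allele_freq: float = 0.9
    farm_allele_freq: float = 0.1
    rates: RateParams = field(default_factory=RateParams)
    spawning: SpawningParams = field(default_factory=SpawningParams)
    straying: StrayingParams = field(default_factory=StrayingParams)
    escapee: EscapeeParams = field(default_factory=EscapeeParams)
    initial: InitialPopulation = field(default_factory=InitialPopulation)
    # 1-based loci whose allele frequencies are recorded each November
    tracked_loci: tuple[int, ...] = (1, 2, 5, 10, 20, 21)


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key path."""


def _merge(obj, data: dict, path: str):
    """Recursively apply a dict of overrides onto a dataclass tree."""
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in names:
            raise ConfigError(f"unknown configuration key: {where}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and not isinstance(current, type):
            if not isinstance(value, dict):
                raise ConfigError(f"{where}: expected a mapping")
            _merge(current, value, where)
        elif isinstance(current, tuple):
            cast = int if all(isinstance(v, int) for v in current) else float
            try:
                setattr(obj, key, tuple(cast(v) for v in value))
            except (TypeError, ValueError):
                raise ConfigError(f"{where}: expected a sequence of numbers") from None
        elif isinstance(current, np.ndarray):
            arr = np.asarray(value, dtype=float)
            if arr.shape != current.shape:
                raise ConfigError(f"{where}: expected shape {current.shape}")
            setattr(obj, key, arr)
        elif isinstance(current, bool):
            if not isinstance(value, bool):
                raise ConfigError(f"{where}: expected a boolean")
            setattr(obj, key, value)
        elif isinstance(current, (int, float)):
            if not isinstance(value, (int, float)):
                raise ConfigError(f"{where}: expected a number")
            setattr(obj, key, type(current)(value))
        else:
            setattr(obj, key, value)


_PROBABILITY_KEYS = [
    ("wild_allele_freq",),
    ("farm_allele_freq",),
    ("straying", "stray_fraction"),
    ("straying", "incoming_wild_freq"),
    ("spawning", "adult_postspawn_mortality"),
    ("spawning", "parr_share_mean"),
    ("rates", "mortality", "alevin_monthly"),
    ("rates", "mortality", "smolt_monthly"),
    ("rates", "mortality", "marine_m_inf"),
    ("escapee", "wild_allele_freq"),
]


def _get_path(cfg, keys):
    obj = cfg
    for k in keys:
        obj = getattr(obj, k)
    return obj


def validate(cfg: SimConfig) -> SimConfig:
    for keys in _PROBABILITY_KEYS:
        v = _get_path(cfg, keys)
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{'.'.join(keys)} must be in [0, 1], got {v}")
    for tup_keys in [("rates", "mortality", "juv_warm"), ("rates", "mortality", "juv_rest")]:
        for i, v in enumerate(_get_path(cfg, tup_keys)):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{'.'.join(tup_keys)}[{i}] must be in [0, 1], got {v}")
    lo, hi = cfg.spawning.parr_prespawn_mortality_range
    if not 0 <= lo <= hi <= 1:
        raise ConfigError("spawning.parr_prespawn_mortality_range must be within [0, 1]")
    if cfg.genetics_decay <= 0:
        raise ConfigError("genetics_decay must be positive")
    if cfg.environment.river_area_m2 <= 0:
        raise ConfigError("environment.river_area_m2 must be positive")
    if not 0 < cfg.spawning.escapee_success_factor <= 1:
        raise ConfigError("spawning.escapee_success_factor must be in (0, 1]")
    return cfg


def default_config() -> SimConfig:
    """The shipped calibrated configuration."""
    cfg = SimConfig()
    path = resources.files("ibsem").joinpath("data/default_config.yaml")
    if path.is_file():
        data = yaml.safe_load(path.read_text()) or {}
        _merge(cfg, data, "")
    return validate(cfg)


def load_and_validate(path: str | Path | None = None) -> SimConfig:
    """Load a YAML config, merge it over the shipped defaults, validate."""
    cfg = default_config()
    if path is not None:
        p = Path(path)
        if not p.is_file():
            raise ConfigError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("top-level configuration must be a mapping")
        _merge(cfg, data, "")
    return validate(cfg)


def to_dict(cfg) -> dict:
    """Plain-python nested dict (YAML-serializable) of a config tree."""
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            out[f.name] = to_dict(v)
        elif isinstance(v, np.ndarray):
            out[f.name] = [float(x) for x in v]
        elif isinstance(v, tuple):
            cast = int if all(isinstance(x, int) for x in v) else float
            out[f.name] = [cast(x) for x in v]
        else:
            out[f.name] = v
    return out


_DUMP_HEADER = """\
# ibsem configuration.
# Provenance: structural constants (21 loci with a neutral 21st, wild/farm/
# strayer allele frequencies 0.9/0.1/0.8, 5% straying, 90 mm smolting
# threshold with 50% probability at 103 mm, parr share Gaussian(0.30, 0.10),
# mate caps 2 adults + 5 parr, seasonal calendar, Table-style initial
# abundances and lengths) are reference-stated; every growth/mortality/
# maturation coefficient and the fecundity slope are outputs of the shipped
# calibration procedure (`ibsem calibrate`).
"""


def dump(cfg: SimConfig, path: str | Path) -> None:
    Path(path).write_text(_DUMP_HEADER + yaml.safe_dump(to_dict(cfg), sort_keys=False))


def make_fixture_population(n_parr: int = 100, n_adults: int = 20, seed: int = 0):
    """Small deterministic population for unit tests (noise off).

    Parr are split evenly over p0/p1/p2 at the configured mean lengths; the
    adults are spread uniformly over sea ages.
    """
    from .engine import ScenarioSpec, initialize_population

    cfg = default_config()
    cfg.initial.n_p0 = cfg.initial.n_p1 = cfg.initial.n_p2 = n_parr // 3 + (
        n_parr - 3 * (n_parr // 3)
    ) / 3.0
    base = n_parr // 3
    cfg.initial.n_p0 = base + n_parr - 3 * base
    cfg.initial.n_p1 = cfg.initial.n_p2 = base
    cfg.initial.n_adult = n_adults
    cfg.initial.len_sd_p0_mm = 0.0
    cfg.initial.len_sd_parr_mm = 0.0
    cfg.initial.len_sd_adult_frac = 0.0
    spec = ScenarioSpec(1, years=1, monitor_start=0, replicates=1)
    state = initialize_population(spec, cfg, seed)
    return state.pop
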
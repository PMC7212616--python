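"""Configuration objects for data generation and analysis runs.

Both configurations are plain dataclasses with YAML round-trip support.  The
schema is versioned (``schema_version``) so persisted run manifests stay
interpretable if defaults evolve.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

SCHEMA_VERSION = 1


@dataclass
class GenerationConfig:
    """Parameters of the synthetic input generator.

    The defaults emulate the study conditions: a closed population of about
    17 million with a stationary age structure, a population-average total
    meat intake of 107 g/day and fruit-and-vegetables intake of 250 g/day,
    five chronic diseases, and per-kg prices/footprints of realistic
    magnitude for the Dutch food market.
    """

    #: target total population; default chosen so that 665,581,000 kg of meat
    #: per year corresponds to 39.2 kg per person per year
    total_population: float = 16_979_107.0
    population_bounds: tuple[float, float] = (16e6, 18e6)
    #: population-weighted mean intakes, g/day
    meat_intake_target: float = 107.0
    fv_intake_target: float = 250.0
    #: split of total meat over (red, processed, poultry)
    meat_split: tuple[float, float, float] = (0.45, 0.30, 0.25)
    #: gamma shape of the within-cell intake distribution
    gamma_shape: float = 4.0
    #: sd of the lognormal cell-level noise on intake age profiles
    intake_noise_sd: float = 0.03
    #: Gompertz-Makeham background mortality: makeham + a * exp(b * age)
    mortality_makeham: float = 2.0e-4
    mortality_a_female: float = 1.8e-5
    mortality_a_male: float = 3.2e-5
    mortality_b: float = 0.105
    #: global multiplier on background mortality (0 gives an immortal cohort)
    mortality_scale: float = 1.0
    #: annual newborn inflow; None derives it from the stationary population
    newborns_per_year: float | None = None
    male_birth_fraction: float = 0.512

    def validate(self) -> None:
        if self.total_population <= 0:
            raise ConfigError("total_population must be positive")
        if not 0 < self.gamma_shape < float("inf"):
            raise ConfigError("gamma_shape must be a positive finite number")
        if self.meat_intake_target < 0 or self.fv_intake_target < 0:
            raise ConfigError("intake targets must be non-negative")
        if abs(sum(self.meat_split) - 1.0) > 1e-9 or min(self.meat_split) < 0:
            raise ConfigError("meat_split must be non-negative and sum to 1")
        if self.mortality_scale < 0:
            raise ConfigError("mortality_scale must be >= 0")
        if self.newborns_per_year is not None and self.newborns_per_year < 0:
            raise ConfigError("newborns_per_year must be >= 0")
        if not 0 <= self.male_birth_fraction <= 1:
            raise ConfigError("male_birth_fraction must lie in [0, 1]")


@dataclass
class AnalysisConfig:
    """Parameters of an SCBA run (everything downstream of the inputs)."""

    base_year: int = 2018
    horizon_years: int = 30
    elasticity_form: str = "iso_elastic"  # or "linear"
    discount_rate: float = 0.03
    qaly_value: float = 50_000.0
    qaly_value_high: float = 100_000.0
    n_iter: int = 100
    working_age: tuple[int, int] = (15, 75)
    productivity_method: str = "human_capital"  # or "friction"
    #: share of the productivity stream accruing to consumers (rest: government)
    productivity_consumer_share: float = 0.13
    perfect_information: bool = False
    #: environmental efficiency gain, fraction of base-year intensity per year
    efficiency_gain: float = 0.0125
    efficiency_gain_high: float = 0.0175
    efficiency_gain_low: float = 0.0075
    #: multiplier on environmental unit costs (1.0 = central estimates)
    unit_cost_factor: float = 1.0
    unit_cost_factor_high: float = 2.0
    unit_cost_factor_low: float = 0.5
    generation: GenerationConfig = field(default_factory=GenerationConfig)

    def validate(self) -> None:
        if self.horizon_years < 1:
            raise ConfigError("horizon_years must be >= 1")
        if self.elasticity_form not in ("iso_elastic", "linear"):
            raise ConfigError(f"unknown elasticity_form {self.elasticity_form!r}")
        if self.discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")
        if self.qaly_value <= 0 or self.qaly_value_high <= 0:
            raise ConfigError("QALY values must be positive")
        if self.n_iter < 0:
            raise ConfigError("n_iter must be >= 0")
        if self.productivity_method not in ("human_capital", "friction"):
            raise ConfigError(f"unknown productivity_method {self.productivity_method!r}")
        if not 0 <= self.productivity_consumer_share <= 1:
            raise ConfigError("productivity_consumer_share must lie in [0, 1]")
        lo, hi = self.working_age
        if not 0 <= lo < hi <= 100:
            raise ConfigError("working_age must satisfy 0 <= lo < hi <= 100")
        self.generation.validate()


def _to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def conv(x):
        if isinstance(x, tuple):
            return [conv(v) for v in x]
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, list):
            return [conv(v) for v in x]
        return x

    return conv(d)


def config_to_yaml(cfg: AnalysisConfig, path: str | Path | None = None) -> str:
    """Serialize an :class:`AnalysisConfig` to YAML (schema-versioned)."""
    doc = {"schema_version": SCHEMA_VERSION, "analysis": _to_dict(cfg)}
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_yaml(src: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file or YAML string."""
    p = Path(src) if not str(src).lstrip().startswith(("schema_version", "{", "analysis")) else None
    text = p.read_text() if p is not None and p.exists() else str(src)
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "analysis" not in doc:
        raise ConfigError("YAML document must contain an 'analysis' mapping")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    data = dict(doc["analysis"])
    gen = data.pop("generation", {})
    try:
        gcfg = GenerationConfig(**{k: _maybe_tuple(v) for k, v in gen.items()})
        cfg = AnalysisConfig(generation=gcfg, **{k: _maybe_tuple(v) for k, v in data.items()})
    except TypeError as exc:  # unknown key
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def _maybe_tuple(v):
    return tuple(v) if isinstance(v, list) else v


def config_hash(cfg: AnalysisConfig) -> str:
    """Stable sha256 digest of a configuration, for run manifests."""
    blob = json.dumps(_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
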
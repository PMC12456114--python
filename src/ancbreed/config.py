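"""Run configuration: nested parameter blocks with YAML/JSON loading.

Defaults follow the simulated wildcat-program scenario throughout: capacity
N = 150, genome of D = 5 Morgans at L = 500 SNPs, delta = 0.5, Poisson
offspring mean 4.2, full compliance, a two-generation introgression pulse of
0.2 ten generations before captivity, bottleneck and captive-selection
fractions of 0.25, source drift parameters 0.2 (F_ST 0.4), and a 20
generation breeding horizon.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .demography import DemographyConfig
from .genome import GenomeMap
from .program import BreedingConfig
from .wildhistory import WildHistoryConfig

__all__ = ["GenomeConfig", "RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class GenomeConfig:
    L: int = 500
    D: float = 5.0

    def genome_map(self) -> GenomeMap:
        return GenomeMap(self.L, self.D)


@dataclass(frozen=True)
class RunConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    wild: WildHistoryConfig = field(default_factory=WildHistoryConfig)
    breeding: BreedingConfig = field(default_factory=BreedingConfig)
    demography: DemographyConfig = field(default_factory=DemographyConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_BLOCKS = {
    "genome": GenomeConfig,
    "wild": WildHistoryConfig,
    "breeding": BreedingConfig,
    "demography": DemographyConfig,
}


def _build_block(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML (or JSON) run file; ``overrides`` maps block->field->value."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping of blocks")
    unknown = set(data) - set(_BLOCKS)
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    merged = {k: dict(v or {}) for k, v in data.items()}
    for block, fields_ in (overrides or {}).items():
        merged.setdefault(block, {}).update(
            {k: v for k, v in fields_.items() if v is not None}
        )
    kwargs = {
        name: _build_block(cls, merged.get(name, {})) for name, cls in _BLOCKS.items()
    }
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the resolved configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
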
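"""Validated pipeline configuration (YAML-backed, strict keys)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class SimulateConfig:
    scale: int = 1500
    capture_rate: float | None = None   # None -> calibrate to target_mids_per_dnb
    target_mids_per_dnb: float = 1.3
    artifact: bool = False
    side_asymmetry: float = 1.0
    seed: int = 0


@dataclass
class FilterConfig:
    min_mid: int = 30


@dataclass
class PcaConfig:
    n_components: int = 50
    seed: int = 0


@dataclass
class GraphConfig:
    k: int = 15
    lam: float = 0.5


@dataclass
class LeidenConfig:
    resolution: float = 1.0
    seed: int = 0


@dataclass
class MarkersConfig:
    top_k: int = 5


@dataclass
class PermConfig:
    M: int = 500_000
    level: float = 0.999
    K: int | None = None        # None -> number of tests executed
    f: float = 0.05
    floor_min: int = 20
    seed: int = 0
    macro_groups: bool = True   # contrast 4 macro tissue groups, not 8 zones


@dataclass
class PipelineConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    bin_size: int = 50
    filter: FilterConfig = field(default_factory=FilterConfig)
    pca: PcaConfig = field(default_factory=PcaConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    leiden: LeidenConfig = field(default_factory=LeidenConfig)
    markers: MarkersConfig = field(default_factory=MarkersConfig)
    perm: PermConfig = field(default_factory=PermConfig)
    gem_path: str | None = None     # run on an existing GEM instead of simulating

    def validate(self) -> "PipelineConfig":
        if self.bin_size < 1:
            raise ConfigError("bin_size must be >= 1")
        if not (0 <= self.graph.lam <= 1):
            raise ConfigError("graph.lam must be in [0, 1]")
        if not (0 < self.perm.f <= 1):
            raise ConfigError("perm.f must be in (0, 1]")
        if not (0 < self.perm.level < 1):
            raise ConfigError("perm.level must be in (0, 1)")
        if self.filter.min_mid < 0:
            raise ConfigError("filter.min_mid must be >= 0")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


_SECTIONS = {
    "simulate": SimulateConfig,
    "filter": FilterConfig,
    "pca": PcaConfig,
    "graph": GraphConfig,
    "leiden": LeidenConfig,
    "markers": MarkersConfig,
    "perm": PermConfig,
}


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a config from nested dicts, rejecting unknown keys."""
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        valid = set(cls.__dataclass_fields__)
        unknown = set(section) - valid
        if unknown:
            raise ConfigError(f"unknown key(s) in {name!r}: {sorted(unknown)}")
        kwargs[name] = cls(**section)
    for key in ("bin_size", "gem_path"):
        if key in data:
            kwargs[key] = data.pop(key)
    if data:
        raise ConfigError(f"unknown top-level key(s): {sorted(data)}")
    return PipelineConfig(**kwargs).validate()


def load_config(path) -> PipelineConfig:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
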
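"""Declarative configuration: one file, sections per pipeline stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .model import ModelConfig
from .synth import BehavioralSimSpec, NeuralSimSpec, PhaseEffectSpec


@dataclass(frozen=True)
class ProtocolConfig:
    phase_grid_size: int = 16
    n_train_events: int = 5
    soas: tuple = tuple(np.linspace(0.1, 0.42, 12))
    n_random_phase_trials: int = 1000
    reduction_grid: tuple = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
    phase_diff_reduction: float = 0.45


@dataclass(frozen=True)
class StatsConfig:
    sinusoid_frequency: float = 6.25
    n_perm_behavior: int = 10000
    n_perm_maps: int = 100
    n_perm_cluster: int = 1000
    cluster_alpha: float = 0.05
    morlet_cycles: float = 5.0
    frequencies: tuple = tuple(np.arange(1.0, 15.5, 1.0))
    times: tuple = tuple(np.round(np.arange(-0.5, 0.0001, 0.02), 3))


@dataclass(frozen=True)
class StudyConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    protocols: ProtocolConfig = field(default_factory=ProtocolConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    behavioral: BehavioralSimSpec = field(default_factory=BehavioralSimSpec)
    neural: NeuralSimSpec = field(default_factory=NeuralSimSpec)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "model": ModelConfig,
    "protocols": ProtocolConfig,
    "stats": StatsConfig,
    "behavioral": BehavioralSimSpec,
    "neural": NeuralSimSpec,
}


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    data = dict(data)
    if cls is NeuralSimSpec and "effects" in data:
        data["effects"] = tuple(
            e if isinstance(e, PhaseEffectSpec) else PhaseEffectSpec(**e)
            for e in data["effects"])
    # YAML has no tuples; coerce lists into the tuple-typed fields
    for f in fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)


def load_config(path=None, overrides: dict | None = None) -> StudyConfig:
    """Load a StudyConfig from YAML; ``overrides`` maps section.field -> value."""
    raw = {}
    if path is not None:
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
    for key, value in (overrides or {}).items():
        section, _, name = key.partition(".")
        if not name:
            raw[section] = value
        else:
            raw.setdefault(section, {})[name] = value
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in raw:
            kwargs[section] = _build(cls, raw[section] or {})
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return StudyConfig(**kwargs)


def config_to_yaml(config: StudyConfig) -> str:
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return _clean(obj.tolist())
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return yaml.safe_dump(_clean(config.to_dict()), sort_keys=False)
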
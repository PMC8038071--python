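"""Flat, human-editable YAML run configuration covering every pipeline stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .model import ArchConfig, TrainConfig
from .preprocess import PreprocessConfig
from .recurrence import EmbeddingConfig
from .synthetic import SimConfig


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    arch: ArchConfig = field(default_factory=ArchConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    balance_mode: str = "fold"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "embedding": EmbeddingConfig,
    "arch": ArchConfig,
    "train": TrainConfig,
    "sim": SimConfig,
}

# fields stored as YAML lists but typed as tuples
_TUPLE_FIELDS = {
    ("arch", "block_filters"), ("arch", "convs_per_block"), ("sim", "route"),
}


def _build_section(section: str, cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in valid:
            raise ConfigError(f"unknown config key {section}.{key}")
        if (section, key) in _TUPLE_FIELDS:
            val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        kwargs[key] = val
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    cfg = RunConfig()
    for key, val in (data or {}).items():
        if key in _SECTIONS:
            setattr(cfg, key, _build_section(key, _SECTIONS[key], val or {}))
        elif key in ("balance_mode", "log_level"):
            setattr(cfg, key, val)
        else:
            raise ConfigError(f"unknown config key {key}")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return config_from_dict(data or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
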
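"""YAML run configuration: one file describing phantom generation,
preprocessing, architecture, loss and training, with unknown keys rejected
so typos fail loudly."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .losses import LossConfig
from .network import ArchConfig
from .optim import AdamConfig, TrainConfig
from .phantom import PhantomConfig

__all__ = ["PreprocessConfig", "RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class PreprocessConfig:
    sigma_spatial: float = 3.0
    sigma_range: float = 0.1
    radius: int | None = None
    levels: int = 256
    denoise: bool = True
    equalize: bool = True


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    arch: ArchConfig = field(default_factory=ArchConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    data_dir: str = "data"
    output_dir: str = "runs"
    seed: int = 0


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys under {path!r}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name == "input_size" and value is not None:
            value = tuple(value)
        if f.name == "optimizer" and isinstance(value, dict):
            value = _build(AdamConfig, value, f"{path}.optimizer")
        kwargs[f.name] = value
    return cls(**kwargs)


_SECTIONS = {
    "phantom": PhantomConfig,
    "preprocess": PreprocessConfig,
    "arch": ArchConfig,
    "loss": LossConfig,
    "train": TrainConfig,
}


def load_config(path) -> RunConfig:
    """Parse a YAML config file into a :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = set(_SECTIONS) | {"data_dir", "output_dir", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {}, name)
    for name in ("data_dir", "output_dir", "seed"):
        if name in raw:
            kwargs[name] = raw[name]
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path) -> str:
    """Write the resolved config next to a run's outputs; returns its hash."""
    data = dataclasses.asdict(cfg)
    data["arch"]["input_size"] = list(data["arch"]["input_size"])
    text = yaml.safe_dump(data, sort_keys=True)
    Path(path).write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
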
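"""Run configuration: one YAML file describing a full pipeline run.

The schema is the nested dataclass tree below; unknown keys anywhere in the
file are rejected so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any

import yaml

from .losses import LossWeights
from .model import ModelConfig
from .phantom import PhantomConfig
from .train import TrainSettings

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised for malformed run-configuration files."""


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainSettings = field(default_factory=TrainSettings)
    n_images: int = 8
    seed: int = 0
    out_dir: str = "runs/default"

    def validate(self) -> None:
        self.phantom.validate()
        self.model.validate()
        self.training.validate()
        if self.n_images < 1:
            raise ConfigError(f"n_images must be >= 1, got {self.n_images}")


def _from_dict(cls, data: Any, path: str):
    if not is_dataclass(cls):
        return data
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got "
                          f"{type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"{path or 'config'}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub = f.type if isinstance(f.type, type) else _resolve(f.type)
        if sub is not None and is_dataclass(sub):
            kwargs[name] = _from_dict(sub, value, f"{path}.{name}" if path else name)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {"phantom": PhantomConfig, "model": ModelConfig,
           "training": TrainSettings, "loss_weights": LossWeights}


def _resolve(type_hint) -> type | None:
    if isinstance(type_hint, str):
        for klass in (PhantomConfig, ModelConfig, TrainSettings, LossWeights):
            if type_hint == klass.__name__:
                return klass
    return None


def _to_plain(obj) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    cfg = _from_dict(RunConfig, raw, "")
    cfg.validate()
    return cfg


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))
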
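"""Strict YAML configuration for full runs.

A ``RunConfig`` nests the model, training, preprocessing and cascade
parameter groups.  Loading is strict: unknown keys are rejected with an
error naming the offending (dotted) key, omitted keys fall back to the
defaults, and a dump/load round trip reproduces the config exactly.
"""

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .network import ModelConfig
from .training import TrainConfig
from .volume_io import PreprocessSpec

__all__ = [
    "CascadeConfig",
    "PathsConfig",
    "RunConfig",
    "load_config",
    "dump_config",
]


@dataclass
class CascadeConfig:
    margin: int = 20
    vote_threshold: float = 0.5

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if not 0 < self.vote_threshold <= 1:
            raise ValueError("vote_threshold must be in (0, 1]")


@dataclass
class PathsConfig:
    input: Optional[str] = None
    output: Optional[str] = None


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)


_TUPLE_FIELDS = {"in_size", "target_size", "shape"}


def _build(cls, data, prefix):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config section {prefix or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        dotted = f"{prefix}{key}"
        if key not in fields:
            raise ValueError(f"unknown config key: {dotted}")
        f = fields[key]
        if isinstance(f.type, type) and dataclasses.is_dataclass(f.type):
            kwargs[key] = _build(f.type, value, f"{dotted}.")
        elif key in _TUPLE_FIELDS:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid config section {prefix or '<root>'}: {e}") from e


def load_config(path: str) -> RunConfig:
    """Load a RunConfig from YAML; missing keys take defaults, unknown
    keys raise a ValueError naming the key."""
    with open(path) as f:
        data = yaml.safe_load(f)
    return _build(RunConfig, data or {}, "")


def dump_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(cfg), f, sort_keys=False)
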
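"""Run configuration: YAML schema over the model, training, and protocol
dataclasses, with strict key validation, a content hash for provenance,
and single-root-seed fan-out to named per-module generators.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .evaluation import ProtocolConfig
from .model import ModelConfig
from .training import TrainConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config",
           "config_hash", "derive_seed"]


class ConfigError(ValueError):
    """Schema violation; the message lists the offending keys."""


@dataclass(frozen=True)
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    seed: int = 0
    scope_size: int = 32


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {unknown}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in ("model", "train", "protocol"):
            sub = {"model": ModelConfig, "train": TrainConfig,
                   "protocol": ProtocolConfig}[f.name]
            value = _build(sub, value, f"{path}.{f.name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load + validate a YAML run configuration; defaults fill missing
    keys, unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _build(RunConfig, raw, "config")


def _as_dict(cfg: RunConfig) -> dict:
    out = dataclasses.asdict(cfg)

    def convert(obj):
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [convert(v) for v in obj]
        return obj

    return convert(out)


def dump_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_as_dict(cfg), sort_keys=True))
    return path


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash recorded in every artifact this config produces."""
    blob = json.dumps(_as_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def derive_seed(root_seed: int, name: str) -> int:
    """Named child seed below 2**31, stable across runs and platforms."""
    digest = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)
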
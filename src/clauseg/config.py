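"""Run configuration: one YAML file describing every pipeline stage.

A :class:`RunConfig` bundles the phantom generator, preprocessing,
augmentation, network, training and ensemble settings plus output paths.
Unknown keys are rejected so a typo cannot silently fall back to a
default, and every command writes its resolved configuration next to its
outputs, making any run reproducible from that file alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .augment import AugmentationSpec
from .network import LossSpec, NetworkSpec
from .phantom import PhantomSpec
from .preprocess import PreprocSpec
from .train import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_TUPLE_FIELDS = {"grid", "spacing", "crop_size", "scale_range", "input_size",
                 "encoder_filters"}


class ConfigError(ValueError):
    pass


def _build(cls, data: dict[str, Any], section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    kwargs = {}
    for k, v in data.items():
        if k in _TUPLE_FIELDS and isinstance(v, (list, tuple)):
            v = tuple(v)
        if k == "loss" and isinstance(v, dict):
            v = _build(LossSpec, v, f"{section}.loss")
        kwargs[k] = v
    return cls(**kwargs)


def _dump(obj) -> dict[str, Any]:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v):
            v = _dump(v)
        elif isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, Path):
            v = str(v)
        out[f.name] = v
    return out


@dataclass
class RunConfig:
    """Union of all stage specifications plus paths and logging."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    preprocess: PreprocSpec = field(default_factory=PreprocSpec)
    augment: Optional[AugmentationSpec] = field(default_factory=AugmentationSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_subjects: int = 30
    members_per_view: int = 3
    views: tuple[str, ...] = ("axial", "coronal")
    threshold: float = 0.5
    log_level: str = "INFO"

    _SECTIONS = {
        "phantom": PhantomSpec,
        "preprocess": PreprocSpec,
        "augment": AugmentationSpec,
        "network": NetworkSpec,
        "train": TrainConfig,
    }


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> RunConfig:
    """Read a YAML run config; unknown sections or keys raise ConfigError."""
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_names
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for k, v in raw.items():
        if k in RunConfig._SECTIONS and isinstance(v, dict):
            kwargs[k] = _build(RunConfig._SECTIONS[k], v, k)
        elif k == "augment" and v is None:
            kwargs[k] = None
        elif k == "views" and isinstance(v, (list, tuple)):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as YAML."""
    out: dict[str, Any] = {}
    for f in dataclasses.fields(RunConfig):
        if f.name.startswith("_"):
            continue
        v = getattr(config, f.name)
        if dataclasses.is_dataclass(v):
            v = _dump(v)
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
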
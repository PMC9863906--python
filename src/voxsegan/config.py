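"""Structured run configuration (YAML) covering every pipeline stage.

A :class:`RunConfig` nests the phantom, preprocessing, network, loss,
training and evaluation sections.  Loading rejects unknown keys with the
offending dotted path, and ``to_dict``/``from_dict`` round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from .losses import LossConfig
from .networks import DiscriminatorSpec, GeneratorSpec
from .phantom import PhantomConfig
from .trainer import TrainConfig


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class PreprocessConfig:
    normalize: str = "zscore"        # "zscore" | "minmax"
    patch_stride: int | None = None  # defaults to patch_size (no overlap)
    tumour_patches_only: bool = True

    def __post_init__(self):
        if self.normalize not in ("zscore", "minmax"):
            raise ConfigError(f"unknown normalisation {self.normalize!r}")


@dataclass
class EvalConfig:
    stride: int | None = None  # prediction stride; defaults to patch_size
    ssim_window: int = 7


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluate: EvalConfig = field(default_factory=EvalConfig)


_LIST_FIELDS = {"tumour_radius_range", "spacing", "class_intensity_table"}


def _to_plain(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, tuple):
        return list(value)
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    return value


def to_dict(cfg: RunConfig) -> dict:
    out = {}
    for f in fields(cfg):
        section = getattr(cfg, f.name)
        out[f.name] = {g.name: _to_plain(getattr(section, g.name))
                       for g in fields(section)}
    return out


def _build_section(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in allowed:
            raise ConfigError(f"unknown config key {path}.{key}")
        if key in ("tumour_radius_range", "spacing") and value is not None:
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {path}: {exc}") from exc


def from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    section_cls = {f.name: f.type for f in fields(RunConfig)}
    classes = {
        "phantom": PhantomConfig, "preprocess": PreprocessConfig,
        "generator": GeneratorSpec, "discriminator": DiscriminatorSpec,
        "loss": LossConfig, "train": TrainConfig, "evaluate": EvalConfig,
    }
    kwargs = {}
    for key, value in data.items():
        if key not in classes:
            raise ConfigError(f"unknown config key {key}")
        if not isinstance(value, dict):
            raise ConfigError(f"section {key} must be a mapping")
        kwargs[key] = _build_section(classes[key], value, key)
    return RunConfig(**kwargs)


def load(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return from_dict(data)


def save(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=False)
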
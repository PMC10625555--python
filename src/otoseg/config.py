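"""YAML experiment configuration: loading, cross-validation of module
configs, and run manifests for bitwise replay.

A configuration file has up to five sections — ``model``, ``loss``,
``train``, ``heatmap_schedule`` and ``phantom`` — each mirroring the
corresponding dataclass. Unknown keys are rejected with the offending
section and key named. Cross-section constraints (chunk edge divisibility
by 2^levels, schedule monotonicity) are checked at load time so a bad
experiment fails before any compute is spent.

The shipped default configuration mirrors the gold-status setup: global
attention gating, instance normalization, Mish activation, augmentation
protocol beta, heatmap schedule gamma, deep supervision, gradient
accumulation over 15 iterations.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .heatmap import HeatmapSchedule
from .io_core import ValidationError
from .losses import LossConfig
from .model import NetworkConfig
from .phantom import PhantomSpec
from .training import TrainConfig

GOLD_OVERRIDES = {
    "model": {"attention": "global", "norm": "instance", "activation": "mish",
              "deep_supervision": True},
    "train": {"augmentation": "beta", "accumulation": 15},
}


@dataclass
class ExperimentConfig:
    model: NetworkConfig
    loss: LossConfig
    train: TrainConfig
    schedule: HeatmapSchedule
    phantom: PhantomSpec


def _build(section: str, cls, raw: dict):
    if raw is None:
        raw = {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise ValidationError(
            f"unknown key(s) in section '{section}': {sorted(unknown)}"
        )
    kwargs = dict(raw)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            val = kwargs[f.name]
            kwargs[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in val
            )
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"invalid section '{section}': {exc}") from exc


def default_config(gold: bool = True) -> ExperimentConfig:
    model_kw = dict(GOLD_OVERRIDES["model"]) if gold else {}
    train_kw = dict(GOLD_OVERRIDES["train"]) if gold else {}
    cfg = ExperimentConfig(
        model=NetworkConfig(**model_kw),
        loss=LossConfig(),
        train=TrainConfig(**train_kw),
        schedule=HeatmapSchedule(),
        phantom=PhantomSpec(),
    )
    _cross_validate(cfg)
    return cfg


def _cross_validate(cfg: ExperimentConfig):
    cfg.model.validate_chunk(cfg.train.chunk)
    if cfg.schedule.milestones[-1] >= cfg.train.iterations:
        # schedule written for the full-scale run: rescale to this run length
        cfg.schedule = cfg.schedule.scaled(cfg.train.iterations)


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment YAML."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known_sections = {"model", "loss", "train", "heatmap_schedule", "phantom"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ValidationError(f"unknown config section(s): {sorted(unknown)}")
    cfg = ExperimentConfig(
        model=_build("model", NetworkConfig, raw.get("model")),
        loss=_build("loss", LossConfig, raw.get("loss")),
        train=_build("train", TrainConfig, raw.get("train")),
        schedule=_build("heatmap_schedule", HeatmapSchedule, raw.get("heatmap_schedule")),
        phantom=_build("phantom", PhantomSpec, raw.get("phantom")),
    )
    _cross_validate(cfg)
    return cfg


def config_to_dict(cfg: ExperimentConfig) -> dict:
    return {
        "model": dataclasses.asdict(cfg.model),
        "loss": dataclasses.asdict(cfg.loss),
        "train": dataclasses.asdict(cfg.train),
        "heatmap_schedule": dataclasses.asdict(cfg.schedule),
        "phantom": dataclasses.asdict(cfg.phantom),
    }


def write_manifest(path, cfg: ExperimentConfig, seeds: dict,
                   artifacts: dict | None = None) -> Path:
    """Snapshot everything needed to replay a run bitwise on CPU."""
    from . import __version__

    path = Path(path)
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seeds": seeds,
        "config": config_to_dict(cfg),
        "artifacts": artifacts or {},
    }
    for name, p in (artifacts or {}).items():
        if not Path(p).exists():
            raise ValidationError(f"manifest artifact '{name}' missing at {p}")
    path.write_text(json.dumps(manifest, indent=2))
    return path
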
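"""Structured run configuration with lossless YAML round-tripping.

A :class:`RunConfig` aggregates every knob of the pipeline — synthetic
data generation, manifest/split handling, augmentation, and the
distillation training protocol — with defaults matching the reference
protocol, so a train run on user data follows it verbatim out of the
box.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .data import DEFAULT_CLASSES, AugmentConfig
from .engine import DistillConfig
from .losses import FocalParams, LossWeights
from .synthetic import SyntheticConfig

__all__ = ["RunConfig", "load_config", "save_config"]


def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return [float(v) for v in obj]
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _build(cls, data: dict, path: str):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown configuration key(s) {sorted(unknown)} under '{path}'"
        )
    return cls(**data)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, in one serializable object."""

    data_root: str = "data/synthetic"
    output_dir: str = "runs"
    log_level: str = "INFO"
    classes: tuple[str, ...] = DEFAULT_CLASSES
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    augment_training: bool = True
    teacher_checkpoint: str | None = None
    train_teacher: bool = False
    teacher_epochs: int | None = None
    distill: DistillConfig = field(default_factory=DistillConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def to_dict(self) -> dict:
        raw = {
            "data_root": self.data_root,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
            "classes": list(self.classes),
            "ratios": list(self.ratios),
            "augment_training": self.augment_training,
            "teacher_checkpoint": self.teacher_checkpoint,
            "train_teacher": self.train_teacher,
            "teacher_epochs": self.teacher_epochs,
            "distill": asdict(self.distill),
            "augment": asdict(self.augment),
            "synthetic": asdict(self.synthetic),
        }
        return _to_plain(raw)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        names = {f.name for f in fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown configuration key(s) {sorted(unknown)}")

        distill_raw = dict(data.pop("distill", {}))
        lw = _build(LossWeights, dict(distill_raw.pop("loss_weights", {})), "distill.loss_weights")
        focal_raw = dict(distill_raw.pop("focal", {}))
        if "class_weights" in focal_raw:
            focal_raw["class_weights"] = np.asarray(focal_raw["class_weights"], dtype=float)
        fp = _build(FocalParams, focal_raw, "distill.focal")
        distill_raw["loss_weights"] = lw
        distill_raw["focal"] = fp
        distill = _build(DistillConfig, distill_raw, "distill")

        augment = _build(AugmentConfig, _tupled(dict(data.pop("augment", {})), ("mean", "std")), "augment")

        synth_raw = dict(data.pop("synthetic", {}))
        for key in ("class_proportions", "classes", "base_hues", "blob_density", "vein_count"):
            if key in synth_raw:
                synth_raw[key] = tuple(synth_raw[key])
        if "blob_radius" in synth_raw:
            synth_raw["blob_radius"] = tuple(tuple(r) for r in synth_raw["blob_radius"])
        synthetic = _build(SyntheticConfig, synth_raw, "synthetic")

        if "classes" in data:
            data["classes"] = tuple(data["classes"])
        if "ratios" in data:
            data["ratios"] = tuple(data["ratios"])
        return cls(distill=distill, augment=augment, synthetic=synthetic, **data)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RunConfig) and self.to_dict() == other.to_dict()


def _tupled(raw: dict, keys: tuple[str, ...]) -> dict:
    for k in keys:
        if k in raw:
            raw[k] = tuple(raw[k])
    return raw


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} does not hold a mapping")
    return RunConfig.from_dict(data)
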
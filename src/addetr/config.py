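"""Run configuration: pydantic models with strict (unknown-key-rejecting)
YAML serialization.

The training defaults mirror the published protocol (200 epochs, batch
16, AdamW at 1e-4, 640x640 inputs).  ``desk_profile`` returns the small
CPU-trainable configuration used by the test-suite and the ablation
harness: 160x160 images, ~300 training images, 30 epochs, and a model
well under half a million parameters.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .synth import DatasetSpec

__all__ = [
    "BackboneConfig", "NeckConfig", "HeadConfig", "ModelConfig", "LossSettings",
    "LossWeights", "TrainSettings", "DataSettings", "EvalSettings", "RunConfig",
    "load_config", "save_config", "desk_profile", "apply_ablation", "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class BackboneConfig(_Strict):
    kind: Literal["msanet", "baseline"] = "msanet"
    widths: tuple[int, int, int, int, int] = (16, 24, 32, 48, 64)
    depths: tuple[int, int, int] = (1, 1, 1)
    afa_common: Optional[int] = None
    baseline_widths: tuple[int, int, int, int] = (32, 48, 72, 104)
    baseline_blocks: int = 2


class NeckConfig(_Strict):
    kind: Literal["ssaff", "baseline", "identity"] = "ssaff"
    channels: int = 48
    p_sizes: tuple[int, ...] = (4, 2)
    ftd_init: Literal["identity"] = "identity"
    num_heads: int = 4


class HeadConfig(_Strict):
    num_queries: int = 60
    num_layers: int = 2
    num_heads: int = 4
    ffn_mult: int = 2


class ModelConfig(_Strict):
    num_classes: int = 5
    backbone: BackboneConfig = Field(default_factory=BackboneConfig)
    neck: NeckConfig = Field(default_factory=NeckConfig)
    head: HeadConfig = Field(default_factory=HeadConfig)


class LossSettings(_Strict):
    """IPIoUv2 family hyperparameters (lambda 1.3, gamma 0.7)."""

    lambda_: float = 1.3
    gamma: float = 0.7
    eps: float = 1e-7

    @field_validator("lambda_", "gamma")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v


class LossWeights(_Strict):
    cls: float = 1.0
    l1: float = 5.0
    iou: float = 2.0


class TrainSettings(_Strict):
    epochs: int = 200
    batch_size: int = 16
    lr: float = 1e-4
    optimizer: Literal["adamw"] = "adamw"
    image_size: int = 640
    regression_loss: str = "ipiouv2"
    weights: LossWeights = Field(default_factory=LossWeights)
    grad_clip: float = 5.0
    weight_decay: float = 1e-4
    # classification focal loss: alpha > 0.5 favors the rare positives
    focal_alpha: float = 0.75
    focal_gamma: float = 2.0
    warmup_steps: int = 50
    lr_schedule: Literal["cosine", "constant"] = "cosine"

    @field_validator("epochs", "batch_size", "image_size")
    @classmethod
    def _positive_int(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v


class DataSettings(_Strict):
    """Either a directory of a generated dataset, or an inline generator
    spec (the default)."""

    path: Optional[str] = None
    num_classes: int = 5
    total_images: int = 200
    class_weights: Optional[list[float]] = None
    lesion_size_range: tuple[float, float] = (0.02, 0.10)
    contrast_range: tuple[float, float] = (0.35, 0.9)
    occlusion_prob: float = 0.10
    healthy_fraction: float = 0.10
    max_lesions: int = 3

    def to_spec(self, image_size: int, seed: int) -> DatasetSpec:
        return DatasetSpec(
            num_classes=self.num_classes,
            total_images=self.total_images,
            class_weights=self.class_weights,
            lesion_size_range=self.lesion_size_range,
            contrast_range=self.contrast_range,
            occlusion_prob=self.occlusion_prob,
            healthy_fraction=self.healthy_fraction,
            max_lesions=self.max_lesions,
            image_size=image_size,
            seed=seed,
        )


class EvalSettings(_Strict):
    score_threshold: float = 0.25
    iou_threshold: float = 0.5


class RunConfig(_Strict):
    seed: int = 0
    model: ModelConfig = Field(default_factory=ModelConfig)
    loss: LossSettings = Field(default_factory=LossSettings)
    train: TrainSettings = Field(default_factory=TrainSettings)
    data: DataSettings = Field(default_factory=DataSettings)
    eval: EvalSettings = Field(default_factory=EvalSettings)


def load_config(path: Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(json.loads(config.model_dump_json()),
                                         sort_keys=False))


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:12]


def desk_profile(seed: int = 0, **overrides) -> RunConfig:
    """Small CPU profile: 160x160 images, 30 epochs, ~300 train images,
    < 0.5 M parameters."""
    cfg = RunConfig(
        seed=seed,
        model=ModelConfig(
            num_classes=5,
            backbone=BackboneConfig(widths=(8, 16, 24, 32, 40),
                                    baseline_widths=(24, 32, 48, 64),
                                    baseline_blocks=1),
            neck=NeckConfig(channels=32),
            head=HeadConfig(num_queries=30, num_layers=3, num_heads=4),
        ),
        train=TrainSettings(epochs=30, batch_size=8, lr=4e-3, image_size=160),
        data=DataSettings(total_images=429),
    )
    for key, value in overrides.items():
        obj = cfg
        *parents, leaf = key.split(".")
        for p in parents:
            obj = getattr(obj, p)
        setattr(obj, leaf, value)
    return cfg


def apply_ablation(config: RunConfig, msanet: bool = True, ssaff: bool = True,
                   ipiouv2: bool = True) -> RunConfig:
    """Toggle the three components independently (the factor structure of
    the ablation harness): msanet off -> baseline backbone; ssaff off ->
    baseline neck; ipiouv2 off -> plain IoU regression loss."""
    cfg = config.model_copy(deep=True)
    cfg.model.backbone.kind = "msanet" if msanet else "baseline"
    cfg.model.neck.kind = "ssaff" if ssaff else "baseline"
    cfg.train.regression_loss = "ipiouv2" if ipiouv2 else "iou"
    return cfg
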
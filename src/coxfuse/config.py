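"""Declarative run configuration.

One YAML document drives every CLI stage; the schema is validated up front
and unknown keys are rejected so a typo never silently changes a run.
Dotted-path overrides (``--set train.strategy=joint``) patch single keys.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .encoders import ImageEncoderConfig
from .fusion import FusionConfig
from .synthetic import SyntheticConfig
from .training import TrainerConfig

__all__ = ["RunConfig", "load_config", "apply_overrides", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    n_patients: int = 300
    patches_per_patient: int = 8
    image_size: int = 64
    n_genes: int = 200
    module_size: int = 20
    beta_img: float = 1.0
    beta_expr: float = 1.0
    noise_img: float = 0.05
    noise_expr: float = 0.3
    baseline_rate: float = 0.1
    censor_rate: float = 0.2

    def to_synthetic(self, seed: int) -> SyntheticConfig:
        return SyntheticConfig(**self.model_dump(), seed=seed)


class PrepSection(_Section):
    patch_size: int = 224
    min_foreground: float = 0.5
    patches_per_slide: int = 100
    genes_in_rows: bool = True


class TrainSection(_Section):
    strategy: str = "expression"
    batch_size: int = 128
    lr_image: float = 2e-3
    lr_expr: float = 2e-3
    epochs_image: int = 15
    epochs_expr: int = 60
    epochs_early: int = 150
    epochs_joint: int = 15
    patches_per_slide: int = 100
    val_fraction: float = 0.15
    k_folds: int = 3
    image_output_dim: int = 32
    expr_hidden: tuple[int, ...] = (64, 32)
    expr_dropout: float = 0.5
    fusion_lr_image: float = 2e-3
    fusion_lr_expr: float = 5e-4
    fusion_lr_head: float = 1e-2
    early_head_dims: tuple[int, ...] = (64, 1)
    joint_final_dropout: float = 0.8

    def to_trainer(self) -> TrainerConfig:
        fusion = FusionConfig(
            strategy="joint",
            early_head_dims=self.early_head_dims,
            joint_final_dropout=self.joint_final_dropout,
            lr_image=self.fusion_lr_image,
            lr_expr=self.fusion_lr_expr,
            lr_head=self.fusion_lr_head,
        )
        return TrainerConfig(
            image_config=ImageEncoderConfig(output_dim=self.image_output_dim),
            expr_hidden=tuple(self.expr_hidden),
            expr_dropout=self.expr_dropout,
            fusion=fusion,
            batch_size=self.batch_size,
            lr_image=self.lr_image,
            lr_expr=self.lr_expr,
            epochs_image=self.epochs_image,
            epochs_expr=self.epochs_expr,
            epochs_early=self.epochs_early,
            epochs_joint=self.epochs_joint,
            patches_per_slide=self.patches_per_slide,
            val_fraction=self.val_fraction,
            k_folds=self.k_folds,
        )


class RunConfig(_Section):
    seed: int = 0
    out_dir: str = "runs/out"
    cohort_dir: str = "runs/cohort"
    transfer_cohort_dir: str | None = None
    gmt_path: str | None = None
    simulate: SimulateSection = SimulateSection()
    prep: PrepSection = PrepSection()
    train: TrainSection = TrainSection()


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**raw)


def apply_overrides(config: RunConfig, overrides: list[str]) -> RunConfig:
    """Apply ``section.key=value`` overrides; values parsed as YAML."""
    data = config.model_dump()
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form key=value")
        dotted, value = item.split("=", 1)
        keys = dotted.split(".")
        node = data
        for k in keys[:-1]:
            if k not in node:
                raise KeyError(f"unknown config section {k!r} in {dotted!r}")
            node = node[k]
        if keys[-1] not in node:
            raise KeyError(f"unknown config key {dotted!r}")
        node[keys[-1]] = yaml.safe_load(value)
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
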
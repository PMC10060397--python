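"""Unimodal survival models and the three multimodal fusion strategies.

* early fusion — patient-level image features (patch-mean) are concatenated
  with expression features, image first, and a fresh Cox MLP head is trained
  on the merged vector while both upstream encoders stay frozen;
* late fusion — the two unimodal patient risks are merged by a linear
  two-coefficient Cox model fitted on the pair of scores;
* joint fusion — both branch extractors train simultaneously: every sampled
  patch is paired with its patient's expression profile, the concatenated
  features feed one fused Cox head (heavy dropout on the final layer), and
  the single Cox loss backpropagates into both branches at per-branch
  learning rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from . import nn
from .encoders import (ExpressionEncoder, ImageEncoder, images_to_tensor)
from .survival import RiskBatch, cox_loss

__all__ = [
    "FusionConfig",
    "ImageSurvivalModel",
    "ExpressionSurvivalModel",
    "EarlyFusionModel",
    "LateFusionModel",
    "JointFusionModel",
    "early_fusion_forward",
    "late_fusion_forward",
    "joint_forward",
    "fit_linear_cox",
]


@dataclass(frozen=True)
class FusionConfig:
    """Fusion strategy and its head/learning-rate settings.

    Defaults are the desk-scale presets; the full-scale preset is
    early_head_dims=(4096, 2048, 200, 1). The image branch always trains
    at a higher rate than the expression branch (its signal is patch-based
    and dilute), the fused head at the highest rate.
    """

    strategy: str = "early"
    early_head_dims: tuple[int, ...] = (64, 1)
    early_dropout: float = 0.5
    joint_final_dropout: float = 0.8
    lr_image: float = 2e-3
    lr_expr: float = 5e-4
    lr_head: float = 1e-2

    def __post_init__(self) -> None:
        if self.strategy not in ("early", "late", "joint"):
            raise ValueError(f"unknown fusion strategy {self.strategy!r}")
        for d in (self.early_dropout, self.joint_final_dropout):
            if not 0.0 <= d < 1.0:
                raise ValueError("dropouts must be in [0, 1)")
        if self.strategy == "joint":
            for name, lr in (("lr_image", self.lr_image),
                             ("lr_expr", self.lr_expr),
                             ("lr_head", self.lr_head)):
                if lr is None:
                    raise ValueError(f"joint fusion requires {name}")


class ImageSurvivalModel:
    """Patch-based image branch with a linear Cox head; the patient risk is
    the mean of the patch risks."""

    def __init__(self, encoder: ImageEncoder, rng: np.random.Generator) -> None:
        self.encoder = encoder
        self.head = nn.Dense(encoder.output_dim, 1, rng, init="xavier")

    def patch_risks(self, patches_u8: np.ndarray, batch: int = 256) -> np.ndarray:
        """Per-patch risk for a (N, H, W, 3) uint8 stack (evaluation mode)."""
        out = []
        for k in range(0, len(patches_u8), batch):
            x = images_to_tensor(patches_u8[k:k + batch])
            feats = self.encoder.forward(x, train=False)
            out.append(self.head.forward(feats)[:, 0])
        return np.concatenate(out) if out else np.zeros(0)

    def predict_risk(self, images: Mapping[str, np.ndarray],
                     patient_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.patch_risks(images[pid]).mean()
                         for pid in patient_ids])

    def patient_features(self, images: Mapping[str, np.ndarray],
                         patient_ids: Sequence[str]) -> np.ndarray:
        """Patch-mean feature vector per patient (evaluation mode)."""
        feats = []
        for pid in patient_ids:
            x = images_to_tensor(images[pid])
            feats.append(self.encoder.forward(x, train=False).mean(axis=0))
        return np.stack(feats)

    def pixel_gradients(self, patches_u8: np.ndarray) -> np.ndarray:
        """d(risk)/d(standardized pixel input), shape (N, 3, H, W)."""
        x = images_to_tensor(patches_u8)
        feats = self.encoder.forward(x, train=False)
        self.head.forward(feats)
        dfeat = self.head.backward(np.ones((len(x), 1)))
        return self.encoder.backward(dfeat)

    def all_params(self) -> list[np.ndarray]:
        return self.encoder.params() + [self.head.W, self.head.b]


class ExpressionSurvivalModel:
    """Expression MLP branch with a linear Cox head."""

    def __init__(self, encoder: ExpressionEncoder,
                 rng: np.random.Generator) -> None:
        self.encoder = encoder
        self.head = nn.Dense(encoder.output_dim, 1, rng, init="xavier")

    def predict_risk(self, profiles: np.ndarray) -> np.ndarray:
        feats = self.encoder.forward(profiles, train=False)
        return self.head.forward(feats)[:, 0]

    def features(self, profiles: np.ndarray) -> np.ndarray:
        return self.encoder.forward(profiles, train=False)

    def input_gradients(self, profiles: np.ndarray) -> np.ndarray:
        """d(risk)/d(normalized expression input), shape (N, n_genes)."""
        feats = self.encoder.forward(profiles, train=False)
        self.head.forward(feats)
        dfeat = self.head.backward(np.ones((len(profiles), 1)))
        return self.encoder.backward(dfeat)

    def all_params(self) -> list[np.ndarray]:
        return self.encoder.params() + [self.head.W, self.head.b]


class EarlyFusionModel:
    """Frozen branch features concatenated (image first) into a Cox MLP."""

    def __init__(self, image_model: ImageSurvivalModel,
                 expr_model: ExpressionSurvivalModel,
                 config: FusionConfig, rng: np.random.Generator) -> None:
        self.image_model = image_model
        self.expr_model = expr_model
        self.config = config
        dims = config.early_head_dims
        expected = image_model.encoder.output_dim + expr_model.encoder.output_dim
        if dims[0] != expected:
            raise ValueError(f"early head input {dims[0]} != concatenated "
                             f"feature length {expected}")
        layers: list[nn.Layer] = []
        for i in range(len(dims) - 1):
            layers.append(nn.Dropout(config.early_dropout, rng))
            layers.append(nn.Dense(dims[i], dims[i + 1], rng))
            if i < len(dims) - 2:
                layers.append(nn.ReLU())
        self.head = nn.Sequential(layers)

    def fused_features(self, img_feats: np.ndarray,
                       expr_feats: np.ndarray) -> np.ndarray:
        if len(img_feats) != len(expr_feats):
            raise ValueError("feature batch lengths differ")
        return np.concatenate([img_feats, expr_feats], axis=1)

    def predict_risk_from_features(self, img_feats: np.ndarray,
                                   expr_feats: np.ndarray) -> np.ndarray:
        z = self.fused_features(img_feats, expr_feats)
        return self.head.forward(z, train=False)[:, 0]

    def all_params(self) -> list[np.ndarray]:
        return (self.image_model.all_params() + self.expr_model.all_params()
                + self.head.params())


class LateFusionModel:
    """Linear two-coefficient Cox combiner over the unimodal patient risks."""

    def __init__(self, image_model: ImageSurvivalModel,
                 expr_model: ExpressionSurvivalModel) -> None:
        self.image_model = image_model
        self.expr_model = expr_model
        self.weights = np.array([0.5, 0.5])  # (w_img, w_expr) until fitted

    def combine(self, risk_img: np.ndarray, risk_expr: np.ndarray) -> np.ndarray:
        return self.weights[0] * np.asarray(risk_img) \
            + self.weights[1] * np.asarray(risk_expr)

    def fit_combiner(self, risk_img: np.ndarray, risk_expr: np.ndarray,
                     times: np.ndarray, events: np.ndarray) -> None:
        X = np.column_stack([risk_img, risk_expr])
        self.weights = fit_linear_cox(X, times, events)

    def all_params(self) -> list[np.ndarray]:
        return (self.image_model.all_params() + self.expr_model.all_params()
                + [self.weights])


class JointFusionModel:
    """Two branches trained simultaneously into one fused Cox head."""

    def __init__(self, image_encoder: ImageEncoder,
                 expr_encoder: ExpressionEncoder,
                 config: FusionConfig, rng: np.random.Generator) -> None:
        self.image_encoder = image_encoder
        self.expr_encoder = expr_encoder
        self.config = config
        fused_dim = image_encoder.output_dim + expr_encoder.output_dim
        self.final_dropout = nn.Dropout(config.joint_final_dropout, rng)
        self.head = nn.Dense(fused_dim, 1, rng, init="xavier")

    def forward(self, x_img: np.ndarray, x_expr: np.ndarray,
                train: bool = False) -> np.ndarray:
        fi = self.image_encoder.forward(x_img, train=train)
        fe = self.expr_encoder.forward(x_expr, train=train)
        z = np.concatenate([fi, fe], axis=1)
        z = self.final_dropout.forward(z, train=train)
        return self.head.forward(z)[:, 0]

    def backward(self, dscore: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backpropagate per-element score gradients into both branches;
        returns (d_input_img, d_input_expr)."""
        dz = self.head.backward(dscore[:, None])
        dz = self.final_dropout.backward(dz)
        d_img = dz[:, :self.image_encoder.output_dim]
        d_expr = dz[:, self.image_encoder.output_dim:]
        return (self.image_encoder.backward(d_img),
                self.expr_encoder.backward(d_expr))

    def predict_patient_risk(self, images: Mapping[str, np.ndarray],
                             profiles: np.ndarray,
                             patient_ids: Sequence[str]) -> np.ndarray:
        """Evaluation risk per patient = mean over patch-level fused risks."""
        risks = np.empty(len(patient_ids))
        for i, pid in enumerate(patient_ids):
            stack = images_to_tensor(images[pid])
            prof = np.repeat(profiles[i][None], len(stack), axis=0)
            risks[i] = self.forward(stack, prof, train=False).mean()
        return risks

    def expression_gradients(self, images: Mapping[str, np.ndarray],
                             profiles: np.ndarray,
                             patient_ids: Sequence[str]) -> np.ndarray:
        """Per-patient gradient of the fused risk w.r.t. the expression
        input, with the image branch providing its patch-mean context."""
        grads = np.empty_like(profiles)
        for i, pid in enumerate(patient_ids):
            stack = images_to_tensor(images[pid])
            prof = np.repeat(profiles[i][None], len(stack), axis=0)
            self.forward(stack, prof, train=False)
            _, d_expr = self.backward(np.ones(len(stack)) / len(stack))
            grads[i] = d_expr.sum(axis=0)
        return grads

    def all_params(self) -> list[np.ndarray]:
        return (self.image_encoder.params() + self.expr_encoder.params()
                + [self.head.W, self.head.b])


def early_fusion_forward(img_feat: np.ndarray, expr_feat: np.ndarray,
                         head: nn.Sequential | nn.Dense) -> float:
    """Risk for one patient from concatenated features (image first)."""
    z = np.concatenate([np.asarray(img_feat), np.asarray(expr_feat)])[None]
    return float(head.forward(z, train=False)[0, 0])


def late_fusion_forward(risk_img: float, risk_expr: float,
                        weights: np.ndarray) -> float:
    if not (np.isfinite(risk_img) and np.isfinite(risk_expr)):
        raise ValueError("non-finite unimodal risk")
    return float(weights[0] * risk_img + weights[1] * risk_expr)


def joint_forward(patch_pixels: np.ndarray, profile: np.ndarray,
                  model: JointFusionModel) -> float:
    """Fused risk for one (patch, expression-profile) training example."""
    x = images_to_tensor(np.asarray(patch_pixels)[None])
    return float(model.forward(x, np.asarray(profile)[None], train=False)[0])


def fit_linear_cox(X: np.ndarray, times: np.ndarray, events: np.ndarray,
                   ) -> np.ndarray:
    """Maximum-partial-likelihood coefficients of a linear Cox model,
    obtained by minimizing the batch Cox loss over the full cohort."""
    X = np.asarray(X, dtype=float)

    def objective(beta: np.ndarray) -> tuple[float, np.ndarray]:
        loss, grad_f = cox_loss(RiskBatch(scores=X @ beta, times=times,
                                          events=events))
        return loss, X.T @ grad_f

    res = minimize(objective, np.zeros(X.shape[1]), jac=True, method="L-BFGS-B")
    return res.x
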
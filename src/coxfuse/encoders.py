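"""Modality feature extractors feeding Cox output heads.

The image branch is a pluggable contract: any backbone that maps a pixel
raster to a fixed-length feature vector qualifies. The built-in backbone is
a small three-stage convolutional network sized so the whole framework
trains on one CPU in seconds; a deep residual backbone with 2048-dim
penultimate features is the full-scale configuration the contract is
written for. The expression branch is a multi-layer perceptron with ReLU
activations and dropout before each layer.

Patch-level image features or risks are averaged per patient to obtain the
patient-level representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn

__all__ = [
    "ImageEncoderConfig",
    "ExpressionMLPConfig",
    "FeatureVector",
    "ImageEncoder",
    "ExpressionEncoder",
    "encode_patch",
    "encode_expression",
    "aggregate_patient_features",
    "aggregate_patient_risk",
    "images_to_tensor",
    "save_checkpoint",
    "load_checkpoint",
]

# per-channel pixel standardization applied after scaling to [0, 1]
PIXEL_MEAN = np.array([0.7, 0.55, 0.6])
PIXEL_STD = np.array([0.25, 0.25, 0.25])


@dataclass(frozen=True)
class ImageEncoderConfig:
    """Backbone choice and fine-tuning depth for the image branch.

    ``trainable_depth`` counts terminal stages that receive gradients; 0
    freezes the whole encoder (only the Cox head trains), mirroring the
    fine-tune-last-block-only regime of large pretrained backbones.
    """

    backbone: str = "smallconv"
    output_dim: int = 32
    channels: tuple[int, int] = (8, 16)
    trainable_depth: int = 99  # train everything by default at desk scale
    pretrained_source: str | None = None

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")


@dataclass(frozen=True)
class ExpressionMLPConfig:
    """Layer sizes for the expression MLP.

    The full-scale preset is [n_genes, 4096, 2048] with dropout 0.5 before
    each layer; the desk-scale default is [n_genes, 64, 32].
    """

    layer_dims: tuple[int, ...] = (200, 64, 32)
    dropout: float = 0.5
    activation: str = "relu"

    def __post_init__(self) -> None:
        if len(self.layer_dims) < 2:
            raise ValueError("expression MLP needs >= 2 layers")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class FeatureVector:
    modality: str  # image | expression | fused
    values: np.ndarray
    owner: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in ("image", "expression", "fused"):
            raise ValueError(f"unknown modality {self.modality!r}")


def images_to_tensor(patches: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) uint8 -> standardized (N, 3, H, W) float64."""
    x = np.asarray(patches, dtype=np.float64) / 255.0
    x = (x - PIXEL_MEAN) / PIXEL_STD
    return x.transpose(0, 3, 1, 2)


class ImageEncoder:
    """Small convolutional backbone: two conv+pool stages and a dense
    projection to ``output_dim`` features."""

    def __init__(self, config: ImageEncoderConfig, image_size: int,
                 rng: np.random.Generator) -> None:
        if config.backbone != "smallconv":
            raise ValueError(
                f"backbone {config.backbone!r} is not built in; plug in a "
                f"custom encoder implementing the same interface")
        self.config = config
        self.image_size = image_size
        c1, c2 = config.channels
        # stage structure mirrors "freeze all but the last block": stage 0 =
        # first conv, stage 1 = second conv, stage 2 = dense projection
        self.stages = [
            nn.Sequential([nn.Conv2d(3, c1, 4, rng, stride=4), nn.ReLU()]),
            nn.Sequential([nn.Conv2d(c1, c2, 4, rng, stride=4), nn.ReLU()]),
        ]
        flat = self._flat_dim(image_size, c2)
        self.stages.append(nn.Sequential([
            nn.Flatten(), nn.Dense(flat, config.output_dim, rng), nn.ReLU()]))
        self.net = nn.Sequential([s for s in self.stages])

    @staticmethod
    def _flat_dim(size: int, c2: int) -> int:
        s = (size - 4) // 4 + 1   # conv 4x4 stride 4, valid
        s = (s - 4) // 4 + 1
        if s < 1:
            raise ValueError(f"image size {size} too small for the backbone")
        return s * s * c2

    @property
    def output_dim(self) -> int:
        return self.config.output_dim

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def trainable(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Parameters/gradients of the terminal ``trainable_depth`` stages."""
        depth = min(self.config.trainable_depth, len(self.stages))
        keep = self.stages[len(self.stages) - depth:]
        return ([p for s in keep for p in s.params()],
                [g for s in keep for g in s.grads()])

    def params(self) -> list[np.ndarray]:
        return self.net.params()

    def grads(self) -> list[np.ndarray]:
        return self.net.grads()


class ExpressionEncoder:
    """MLP over a normalized expression profile: dropout before each dense
    layer, ReLU activations."""

    def __init__(self, config: ExpressionMLPConfig,
                 rng: np.random.Generator) -> None:
        self.config = config
        layers: list[nn.Layer] = []
        dims = config.layer_dims
        for i in range(len(dims) - 1):
            layers.append(nn.Dropout(config.dropout, rng))
            layers.append(nn.Dense(dims[i], dims[i + 1], rng))
            layers.append(nn.ReLU())
        self.net = nn.Sequential(layers)

    @property
    def input_dim(self) -> int:
        return self.config.layer_dims[0]

    @property
    def output_dim(self) -> int:
        return self.config.layer_dims[-1]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} genes, "
                             f"received {x.shape[1]}")
        return self.net.forward(x, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def params(self) -> list[np.ndarray]:
        return self.net.params()

    def grads(self) -> list[np.ndarray]:
        return self.net.grads()


def encode_patch(patch_pixels: np.ndarray, encoder: ImageEncoder,
                 owner: str = "") -> FeatureVector:
    """One (H, W, 3) uint8 patch -> image FeatureVector (evaluation mode)."""
    p = np.asarray(patch_pixels)
    if p.shape != (encoder.image_size, encoder.image_size, 3):
        raise ValueError(f"patch shape {p.shape} does not match encoder "
                         f"input {(encoder.image_size, encoder.image_size, 3)}")
    x = images_to_tensor(p[None])
    return FeatureVector("image", encoder.forward(x, train=False)[0], owner)


def encode_expression(profile: np.ndarray, encoder: ExpressionEncoder,
                      owner: str = "") -> FeatureVector:
    """One normalized gene profile -> expression FeatureVector."""
    v = np.asarray(profile, dtype=float)
    if v.ndim != 1 or v.shape[0] != encoder.input_dim:
        raise ValueError(f"expected {encoder.input_dim} genes, "
                         f"received {v.shape}")
    return FeatureVector("expression",
                         encoder.forward(v[None], train=False)[0], owner)


def aggregate_patient_features(patch_features: Sequence[FeatureVector],
                               ) -> FeatureVector:
    """Element-wise mean of the patch features of one patient."""
    if len(patch_features) == 0:
        raise ValueError("need at least one feature vector")
    owners = {f.owner for f in patch_features}
    if len(owners) > 1:
        raise ValueError(f"mixed owners in aggregation: {sorted(owners)}")
    lengths = {len(f.values) for f in patch_features}
    if len(lengths) > 1:
        raise ValueError("feature vectors have unequal lengths")
    stacked = np.stack([f.values for f in patch_features])
    return FeatureVector(patch_features[0].modality, stacked.mean(axis=0),
                         patch_features[0].owner)


def aggregate_patient_risk(patch_scores: Sequence[float]) -> float:
    """Mean of the patch-level risk scores of one patient."""
    if len(patch_scores) == 0:
        raise ValueError("need at least one risk score")
    return float(np.mean(patch_scores))


def save_checkpoint(net_params: list[np.ndarray], path: str | Path,
                    config: dict | None = None, seed: int | None = None) -> None:
    """Weights as .npz with a JSON sidecar recording config and seed."""
    path = Path(path)
    np.savez(path, **{f"p{i}": p for i, p in enumerate(net_params)})
    sidecar = {"config": config or {}, "seed": seed, "n_arrays": len(net_params)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_checkpoint(path: str | Path) -> tuple[list[np.ndarray], dict]:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        params = [z[f"p{i}"] for i in range(len(z.files))]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return params, sidecar
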
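"""Histopathology preprocessing.

Tissue is separated from glass background with an Otsu threshold on the HSV
saturation channel (H&E-stained tissue is strongly saturated, glass is
near-grey), the foreground is cut into a non-overlapping grid of square
patches, a fixed number of patches is sampled per slide for training, and a
colour-jitter augmentation perturbs brightness/contrast/saturation/hue to
make models robust to stain variation without stain normalization.

Plain PNG/TIFF rasters are read directly and treated as already being at
extraction resolution; pyramidal slide formats can be plugged in through
``read_region_fn`` style callables supplied by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

__all__ = [
    "TissueMask",
    "Patch",
    "PatchManifest",
    "tissue_mask_otsu",
    "extract_patches",
    "sample_patches",
    "stain_jitter",
    "write_patches",
    "read_patch",
]

PATCH_SIZE_DEFAULT = 224
MANIFEST_COLUMNS = ["patient_id", "slide_id", "x", "y",
                    "foreground_fraction", "path"]


@dataclass
class TissueMask:
    mask: np.ndarray  # boolean raster, True = tissue
    foreground_fraction: float


@dataclass
class Patch:
    """One square RGB tile; origin is (x, y) top-left, grid-aligned."""

    pixels: np.ndarray
    origin: tuple[int, int]
    slide_id: str
    patient_id: str

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] != p.shape[1]:
            raise ValueError(f"patch must be square RGB, got shape {p.shape}")
        if p.dtype != np.uint8:
            raise ValueError("patch pixels must be 8-bit")
        self.pixels = p


class PatchManifest:
    """Tabular bookkeeping of tiles per slide per patient."""

    def __init__(self, frame: pd.DataFrame | None = None) -> None:
        if frame is None:
            frame = pd.DataFrame(columns=MANIFEST_COLUMNS)
        missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"manifest lacks columns {missing}")
        dup = frame.duplicated(subset=["slide_id", "x", "y"])
        if dup.any():
            raise ValueError("duplicate (slide_id, origin) rows in manifest")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PatchManifest":
        return cls(pd.read_csv(path, sep="\t"))


def tissue_mask_otsu(image: np.ndarray) -> TissueMask:
    """Otsu threshold on the HSV saturation channel; low saturation = glass."""
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    sat = rgb2hsv(img)[..., 1]
    if np.ptp(sat) < 1e-9:
        warnings.warn("uniform image: Otsu threshold degenerate, returning "
                      "all-background mask", RuntimeWarning, stacklevel=2)
        mask = np.zeros(sat.shape, dtype=bool)
        return TissueMask(mask=mask, foreground_fraction=0.0)
    thr = threshold_otsu(sat)
    mask = sat > thr
    return TissueMask(mask=mask, foreground_fraction=float(mask.mean()))


def extract_patches(image: np.ndarray,
                    mask: TissueMask,
                    patient_id: str,
                    slide_id: str,
                    patch_size: int = PATCH_SIZE_DEFAULT,
                    min_foreground: float = 0.5,
                    ) -> tuple[list[Patch], PatchManifest]:
    """Tile the foreground into a non-overlapping grid.

    A tile is kept iff its tissue fraction >= ``min_foreground``; partial
    edge tiles are discarded.
    """
    img = np.asarray(image)
    if mask.mask.shape != img.shape[:2]:
        raise ValueError("mask extent does not match image extent")
    h, w = img.shape[:2]
    if h < patch_size or w < patch_size:
        warnings.warn("image smaller than one tile; no patches extracted",
                      RuntimeWarning, stacklevel=2)
        return [], PatchManifest()
    patches: list[Patch] = []
    rows = []
    for y in range(0, h - patch_size + 1, patch_size):
        for x in range(0, w - patch_size + 1, patch_size):
            frac = float(mask.mask[y:y + patch_size, x:x + patch_size].mean())
            if frac >= min_foreground:
                tile = np.ascontiguousarray(
                    img[y:y + patch_size, x:x + patch_size])
                if tile.dtype != np.uint8:
                    tile = np.clip(tile, 0, 255).astype(np.uint8)
                patches.append(Patch(pixels=tile, origin=(x, y),
                                     slide_id=slide_id, patient_id=patient_id))
                rows.append({"patient_id": patient_id, "slide_id": slide_id,
                             "x": x, "y": y, "foreground_fraction": frac,
                             "path": ""})
    return patches, PatchManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


def sample_patches(manifest: PatchManifest, n: int = 100,
                   seed: int = 0) -> PatchManifest:
    """Uniformly sample up to ``n`` patches per slide, without replacement.

    A slide with <= n patches keeps all of them. Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for slide_id, group in manifest.frame.groupby("slide_id", sort=True):
        if len(group) <= n:
            parts.append(group)
        else:
            idx = rng.choice(len(group), size=n, replace=False)
            parts.append(group.iloc[np.sort(idx)])
    if not parts:
        return PatchManifest()
    return PatchManifest(pd.concat(parts, ignore_index=True))


def stain_jitter(patch: Patch, strength: float = 1.0, seed: int = 0) -> Patch:
    """Random brightness/contrast/saturation/hue perturbation.

    At full strength, brightness/contrast/saturation factors are drawn from
    [0.8, 1.2] and the hue is shifted by up to +/-0.05 of the hue circle;
    ``strength`` in [0, 1] scales those ranges linearly (0 = identity).
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError(f"jitter strength must be in [0, 1], got {strength}")
    if strength == 0.0:
        return Patch(pixels=patch.pixels.copy(), origin=patch.origin,
                     slide_id=patch.slide_id, patient_id=patch.patient_id)
    rng = np.random.default_rng(seed)
    b, c, s = 1.0 + strength * rng.uniform(-0.2, 0.2, size=3)
    hue_shift = strength * rng.uniform(-0.05, 0.05)

    img = patch.pixels.astype(np.float64) / 255.0
    img = np.clip(img * b, 0, 1)                           # brightness
    img = np.clip((img - img.mean()) * c + img.mean(), 0, 1)  # contrast
    hsv = rgb2hsv(img)
    hsv[..., 1] = np.clip(hsv[..., 1] * s, 0, 1)           # saturation
    hsv[..., 0] = np.mod(hsv[..., 0] + hue_shift, 1.0)     # hue
    from skimage.color import hsv2rgb
    out = np.clip(hsv2rgb(hsv) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    return Patch(pixels=out, origin=patch.origin,
                 slide_id=patch.slide_id, patient_id=patch.patient_id)


def write_patches(patches: list[Patch], out_dir: str | Path) -> PatchManifest:
    """Write per-patch PNGs and return a manifest with file paths filled in."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patches:
        name = f"{p.slide_id}_x{p.origin[0]}_y{p.origin[1]}.png"
        path = out_dir / name
        Image.fromarray(p.pixels).save(path)
        rows.append({"patient_id": p.patient_id, "slide_id": p.slide_id,
                     "x": p.origin[0], "y": p.origin[1],
                     "foreground_fraction": np.nan, "path": str(path)})
    return PatchManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


def read_patch(path: str | Path, patient_id: str = "", slide_id: str = "",
               origin: tuple[int, int] = (0, 0)) -> Patch:
    pixels = np.asarray(Image.open(path).convert("RGB"))
    return Patch(pixels=pixels, origin=origin,
                 slide_id=slide_id, patient_id=patient_id)
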
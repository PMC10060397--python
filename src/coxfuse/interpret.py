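"""Gradient-based model interpretation.

The risk score of a fitted model is backpropagated to its inputs: per-gene
gradients quantify how each (normalized) expression value pushes the
predicted risk (negative = toward lower risk), pathway importance is the
mean gradient over a gene set's measured members, pathways are ranked by
the sum of absolute gradients across samples, and pixel-level saliency maps
highlight the image regions driving a patch's risk. A two-sample t test
compares externally supplied per-patch cell-type fractions between risk
groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CapabilityError

__all__ = [
    "GeneSetCollection",
    "PathwayGradientTable",
    "read_gmt",
    "gene_gradients",
    "pathway_scores",
    "rank_pathways",
    "patch_saliency",
    "cell_fraction_compare",
]


@dataclass
class GeneSetCollection:
    """Pathway name -> member gene ids, as parsed from a GMT file."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PathwayGradientTable:
    """Pathways x samples mean gene gradients, with the ranking key."""

    pathways: list[str]
    samples: list[str]
    values: np.ndarray

    @property
    def rank_keys(self) -> np.ndarray:
        """Sum of absolute gradients across samples, per pathway."""
        return np.abs(self.values).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pathways,
                            columns=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="pathway")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, member genes)."""
    from gseapy import read_gmt as _read

    sets = _read(str(path))
    if len(sets) == 0:
        raise ValueError(f"no gene sets parsed from {path}")
    return GeneSetCollection(sets={k: list(v) for k, v in sets.items()})


def gene_gradients(model, profiles: np.ndarray, gene_ids: list[str],
                   sample_ids: list[str], **kwargs) -> pd.DataFrame:
    """Genes x samples gradient of the risk w.r.t. normalized expression.

    ``model`` must expose ``input_gradients`` (unimodal expression model) or
    ``expression_gradients`` (joint model, which also needs ``images`` and
    ``patient_ids`` keyword context). Sign is preserved: negative gradients
    indicate a contribution toward a lower predicted risk.
    """
    if hasattr(model, "input_gradients"):
        grads = model.input_gradients(np.asarray(profiles, dtype=float))
    elif hasattr(model, "expression_gradients"):
        grads = model.expression_gradients(profiles=np.asarray(profiles,
                                                               dtype=float),
                                           **kwargs)
    else:
        raise CapabilityError(
            f"{type(model).__name__} exposes no input-gradient interface; "
            f"gradient interpretation needs a differentiable model")
    if grads.shape != (len(sample_ids), len(gene_ids)):
        raise ValueError("gradient shape mismatch")
    return pd.DataFrame(grads.T, index=gene_ids, columns=sample_ids)


def pathway_scores(gradients: pd.DataFrame,
                   sets: GeneSetCollection) -> PathwayGradientTable:
    """Per pathway, per sample: mean gradient over the pathway's measured
    genes. Pathways with no measured gene are dropped with a warning; a
    gene in several pathways contributes to each of them."""
    measured = set(gradients.index)
    names, rows = [], []
    dropped = []
    for name, genes in sets.sets.items():
        present = [g for g in genes if g in measured]
        if not present:
            dropped.append(name)
            continue
        names.append(name)
        rows.append(gradients.loc[present].to_numpy().mean(axis=0))
    if dropped:
        warnings.warn(f"dropping {len(dropped)} pathway(s) with no measured "
                      f"genes: {dropped[:3]}{'...' if len(dropped) > 3 else ''}",
                      RuntimeWarning, stacklevel=2)
    if not names:
        raise ValueError("no pathway has any measured gene")
    return PathwayGradientTable(pathways=names,
                                samples=list(gradients.columns),
                                values=np.stack(rows))


def rank_pathways(table: PathwayGradientTable, k: int = 15) -> pd.DataFrame:
    """Top-k pathways, descending by sum of absolute gradients across
    samples; ties broken deterministically by pathway name."""
    if len(table.pathways) == 0:
        raise ValueError("empty pathway table")
    keys = table.rank_keys
    order = sorted(range(len(keys)),
                   key=lambda i: (-keys[i], table.pathways[i]))
    top = order[:k]
    df = pd.DataFrame(table.values[top], index=[table.pathways[i] for i in top],
                      columns=table.samples)
    df.insert(0, "sum_abs_gradient", keys[top])
    return df


def patch_saliency(model, patch_pixels: np.ndarray,
                   overlay_path: str | Path | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel saliency of one patch: channel-max of |d risk / d pixel|,
    min-max scaled to [0, 1]; the overlay is a 0.5-alpha blend of a heat
    colormap on the original patch. Returns (heatmap, overlay_rgb)."""
    if not hasattr(model, "pixel_gradients"):
        raise CapabilityError(
            f"{type(model).__name__} exposes no pixel-gradient interface")
    p = np.asarray(patch_pixels)
    grads = model.pixel_gradients(p[None])[0]          # (3, H, W)
    heat = np.abs(grads).max(axis=0)
    rng_ = heat.max() - heat.min()
    heat = (heat - heat.min()) / rng_ if rng_ > 0 else np.zeros_like(heat)
    import matplotlib
    colored = matplotlib.colormaps["jet"](heat)[..., :3]
    overlay = np.clip(0.5 * (p / 255.0) + 0.5 * colored, 0, 1)
    overlay = (overlay * 255 + 0.5).astype(np.uint8)
    if overlay_path is not None:
        from PIL import Image
        Image.fromarray(overlay).save(overlay_path)
    return heat, overlay


def cell_fraction_compare(fractions_a: pd.DataFrame,
                          fractions_b: pd.DataFrame,
                          welch: bool = False,
                          fdr: bool = False) -> pd.DataFrame:
    """Two-sample t test per cell type between two groups of patches.

    Inputs are patches x cell-type fraction tables (e.g. from an external
    nucleus segmenter). Student's pooled-variance t by default (df =
    n1 + n2 - 2), Welch optional; an optional Benjamini–Hochberg column is
    off by default. The sign of t follows mean(a) - mean(b).
    """
    common = [c for c in fractions_a.columns if c in fractions_b.columns]
    if not common:
        raise ValueError("no shared cell-type columns")
    if len(fractions_a) < 2 or len(fractions_b) < 2:
        raise ValueError("each group needs >= 2 patches for a t test")
    rows = []
    for cell in common:
        a = fractions_a[cell].to_numpy(dtype=float)
        b = fractions_b[cell].to_numpy(dtype=float)
        res = stats.ttest_ind(a, b, equal_var=not welch)
        df = (res.df if hasattr(res, "df")
              else len(a) + len(b) - 2)
        rows.append({"cell_type": cell, "t": float(res.statistic),
                     "df": float(df), "p": float(res.pvalue),
                     "mean_a": a.mean(), "mean_b": b.mean()})
    out = pd.DataFrame(rows).set_index("cell_type")
    if fdr:
        from statsmodels.stats.multitest import multipletests
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
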
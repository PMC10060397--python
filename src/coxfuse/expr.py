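"""Gene-expression preprocessing.

A genes x samples matrix is filtered for missing values, log2(x+1)
transformed and z-scored per gene across samples, and intersected with a
second cohort's gene list so two cohorts feed encoders with positionally
aligned inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "filter_missing_genes",
    "log_z_transform",
    "intersect_genes",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit normalization flag."""

    gene_ids: list[str]
    samples: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def sample_vector(self, sample: str) -> np.ndarray:
        return self.values[:, self.samples.index(sample)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.samples)


def filter_missing_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop every gene row that contains at least one missing value."""
    keep = ~np.isnan(m.values).any(axis=1)
    if not keep.any():
        raise ValueError("all genes contain missing values; empty matrix")
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        samples=list(m.samples),
        values=m.values[keep],
        normalized=m.normalized,
    )


def log_z_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) then per-gene z-score across samples.

    Genes with zero post-log variance are dropped with a warning. Raises if
    the matrix is already normalized (the transform is not idempotent) or if
    it contains negative count values.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized; transform is not "
                         "idempotent")
    if np.nanmin(m.values) < 0:
        raise ValueError("negative expression values: expected nonnegative "
                         "counts before log transform")
    logged = np.log2(m.values + 1.0)
    sd = logged.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-variance gene(s): "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                      RuntimeWarning, stacklevel=2)
    logged = logged[keep]
    mu = logged.mean(axis=1, keepdims=True)
    sdk = logged.std(axis=1, ddof=0, keepdims=True)
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        samples=list(m.samples),
        values=(logged - mu) / sdk,
        normalized=True,
    )


def intersect_genes(a: ExpressionMatrix,
                    b: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their sorted common gene set, same order."""
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise ValueError("no overlapping genes between the two cohorts")
    ia = [a.gene_ids.index(g) for g in common]
    ib = [b.gene_ids.index(g) for g in common]
    out_a = ExpressionMatrix(common, list(a.samples), a.values[ia], a.normalized)
    out_b = ExpressionMatrix(common, list(b.samples), b.values[ib], b.normalized)
    return out_a, out_b


def read_expression_tsv(path: str | Path, genes_in_rows: bool = True,
                        normalized: bool = False) -> ExpressionMatrix:
    """Read a TSV with gene ids in the first column and sample ids in the
    header (or transposed, with ``genes_in_rows=False``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not genes_in_rows:
        df = df.T
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        normalized=normalized,
    )


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id")
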
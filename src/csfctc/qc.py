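"""Gene- and cell-level quality control on raw counts.

The filters mirror standard Smart-seq2 practice for CSF single-cell data:
genes seen in fewer than 10 cells are dropped; cells with fewer than 600
detected genes or more than 20% mitochondrial reads are dropped; downstream
tumor-cell analyses further restrict to cells with at least 1000 detected
genes.  Boundary semantics are deliberate and tested: "fewer than 600" and
"more than 20%" are strict (a cell at exactly 600 genes and exactly 20% mito
survives), while the high-coverage subset boundary is inclusive (>= 1000).

The mitochondrial fraction is computed over counted reads — the only
information a count matrix carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountMatrix


@dataclass
class QCMetrics:
    """Per-cell and per-gene QC metrics computed on raw counts."""

    per_cell: pd.DataFrame  # index cell_id; genes_detected, total_counts, mito_fraction
    per_gene: pd.Series  # index gene_id; cells_expressing


def default_mito_genes(gene_ids: list[str]) -> list[str]:
    """Genes whose symbol starts with 'MT-' (override with an explicit list)."""
    return [g for g in gene_ids if g.startswith("MT-")]


def compute_qc(cm: CountMatrix, mito_genes: list[str] | None = None) -> QCMetrics:
    """Detected genes, total counts, and mitochondrial fraction per cell."""
    if mito_genes is None:
        mito_genes = default_mito_genes(cm.gene_ids)
    detected = cm.counts > 0
    genes_detected = detected.sum(axis=0)
    total = cm.counts.sum(axis=0)
    mito_set = set(mito_genes)
    mito_mask = np.array([g in mito_set for g in cm.gene_ids], dtype=bool)
    mito_counts = cm.counts[mito_mask, :].sum(axis=0) if mito_mask.any() else np.zeros(cm.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    per_cell = pd.DataFrame(
        {
            "genes_detected": genes_detected.astype(int),
            "total_counts": total.astype(int),
            "mito_fraction": mito_fraction.astype(float),
        },
        index=pd.Index(cm.cell_ids, name="cell_id"),
    )
    per_gene = pd.Series(
        detected.sum(axis=1).astype(int),
        index=pd.Index(cm.gene_ids, name="gene_id"),
        name="cells_expressing",
    )
    return QCMetrics(per_cell=per_cell, per_gene=per_gene)


def filter_genes(cm: CountMatrix, min_cells: int = 10) -> CountMatrix:
    """Keep genes detected in at least ``min_cells`` cells ("less than 10" dropped)."""
    if min_cells < 0:
        raise ValidationError("min_cells must be >= 0")
    cells_expressing = (cm.counts > 0).sum(axis=1)
    return cm.subset_genes(cells_expressing >= min_cells)


def filter_cells(
    cm: CountMatrix,
    qc: QCMetrics,
    min_genes: int = 600,
    max_mito: float = 0.20,
) -> CountMatrix:
    """Remove a cell iff genes_detected < min_genes OR mito_fraction > max_mito.

    Both boundaries are strict: exactly ``min_genes`` detected genes and
    exactly ``max_mito`` mitochondrial fraction are retained.
    """
    per_cell = qc.per_cell.loc[cm.cell_ids]
    fail = (per_cell["genes_detected"].to_numpy() < min_genes) | (
        per_cell["mito_fraction"].to_numpy() > max_mito
    )
    return cm.subset_cells(~fail)


def subset_high_coverage(cm: CountMatrix, qc: QCMetrics, min_genes: int = 1000) -> CountMatrix:
    """Keep cells with genes_detected >= min_genes (inclusive boundary)."""
    per_cell = qc.per_cell.loc[cm.cell_ids]
    return cm.subset_cells(per_cell["genes_detected"].to_numpy() >= min_genes)


def run_qc(
    cm: CountMatrix,
    min_cells: int = 10,
    min_genes: int = 600,
    max_mito: float = 0.20,
    mito_genes: list[str] | None = None,
) -> tuple[CountMatrix, QCMetrics]:
    """Pipeline default: filter genes first, then cells, on fresh metrics."""
    cm = filter_genes(cm, min_cells=min_cells)
    qc = compute_qc(cm, mito_genes=mito_genes)
    cm = filter_cells(cm, qc, min_genes=min_genes, max_mito=max_mito)
    return cm, qc
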
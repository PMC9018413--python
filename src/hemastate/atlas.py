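"""Single-cell QC, normalization and reference-profile construction.

The reference atlas is distilled from a labeled single-cell count matrix
in three steps: cells are filtered on detected-gene count and
mitochondrial content, library sizes are normalized with a log1p
transform (for the matcher), and per-type raw-count frequency profiles
are built (for the deconvolution likelihood, which operates on counts).
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from .containers import CellMatrix, ReferenceProfiles

__all__ = ["qc_filter", "normalize_log1p", "build_profiles"]


def qc_filter(cells: CellMatrix, min_genes: int = 200,
              max_mito: float = 0.20) -> CellMatrix:
    """Keep cells expressing strictly more than ``min_genes`` genes and with
    mitochondrial count share strictly below ``max_mito``.

    A gene counts as detected when its count is >= 1. Cell order is
    preserved; an empty result warns rather than errors.
    """
    counts = cells.counts.tocsc()
    detected = (counts > 0).sum(axis=0).A1
    totals = counts.sum(axis=0).A1
    mito = cells.mito_mask()
    mito_counts = counts[mito, :].sum(axis=0).A1 if mito.any() else np.zeros_like(totals)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_share = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
    keep = (detected > min_genes) & (mito_share < max_mito)
    if not keep.any():
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return cells.subset_cells(keep)


def normalize_log1p(cells: CellMatrix, target_sum: float = 10_000) -> CellMatrix:
    """Scale each cell to ``target_sum`` total counts, then apply log1p.

    Zeros stay exactly zero, so sparsity is preserved. Cells with zero
    total counts must have been removed by QC first.
    """
    counts = cells.counts.tocsc().astype(float)
    totals = counts.sum(axis=0).A1
    if (totals <= 0).any():
        raise ValueError("zero-total cell encountered; run qc_filter first")
    scale = sp.diags(target_sum / totals)
    norm = (counts @ scale).tocsr()
    norm.data = np.log1p(norm.data)
    return CellMatrix(counts=norm, gene_ids=cells.gene_ids,
                      cell_ids=cells.cell_ids, labels=cells.labels,
                      mito_genes=cells.mito_genes)


def build_profiles(cells: CellMatrix,
                   lineage_tags: dict | None = None) -> ReferenceProfiles:
    """Distill a labeled raw-count matrix into per-type frequency profiles.

    Each profile column is the sum of raw counts over that type's cells,
    normalized to sum 1. Profiles are built from raw counts (not
    log-normalized values) because the deconvolution likelihood is on
    counts. Gene order follows the matrix.
    """
    if cells.labels is None:
        raise ValueError("build_profiles requires cell-type labels")
    types = sorted(set(cells.labels))
    counts = cells.counts.tocsc()
    labels = np.asarray(cells.labels)
    cols = []
    for t in types:
        summed = counts[:, labels == t].sum(axis=1).A1
        tot = summed.sum()
        if tot <= 0:
            raise ValueError(f"cell type {t!r} has all-zero summed counts")
        cols.append(summed / tot)
    tags = dict(lineage_tags or {})
    return ReferenceProfiles(profile=np.column_stack(cols),
                             gene_ids=cells.gene_ids, cell_type_names=types,
                             lineage_tags={t: tags.get(t, "") for t in types})
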
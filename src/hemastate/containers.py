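"""Core in-memory containers shared across the pipeline.

Two objects travel between almost every stage:

``CellMatrix``
    A sparse genes x cells count (or normalized-expression) matrix with
    gene/cell identifiers, optional per-cell type labels, and a designated
    set of mitochondrial genes used by quality control.

``ReferenceProfiles``
    The distilled atlas: a genes x cell-type matrix of expression
    frequencies (each column sums to 1), lineage tags per type, and
    optional non-negative per-gene weights consumed by the deconvolution
    likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["CellMatrix", "ReferenceProfiles"]


@dataclass
class CellMatrix:
    """Sparse genes x cells expression matrix with metadata.

    ``counts`` holds raw non-negative integers straight from a generator or
    an MTX file; after :func:`hemastate.atlas.normalize_log1p` it holds
    non-negative floats. ``mito_genes`` is the subset of ``gene_ids``
    treated as mitochondrial for QC.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    labels: np.ndarray | None = None
    mito_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("expression matrix has negative entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.cell_ids):
                raise ValueError("labels must cover all cells")
        self.mito_genes = frozenset(self.mito_genes)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def mito_mask(self) -> np.ndarray:
        """Boolean mask over genes marking the mitochondrial subset."""
        return np.array([g in self.mito_genes for g in self.gene_ids], dtype=bool)

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        """Return a new matrix restricted to the selected cells (order kept)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            labels=None if self.labels is None else self.labels[idx],
            mito_genes=self.mito_genes,
        )

    # ------------------------------------------------------------------ IO
    def write(self, prefix: str) -> None:
        """Write ``<prefix>matrix.mtx``, ``genes.tsv``, ``barcodes.tsv`` and,
        when labels are present, ``labels.tsv``."""
        mmwrite(f"{prefix}matrix.mtx", sp.coo_matrix(self.counts))
        pd.DataFrame({"gene": self.gene_ids,
                      "mito": [int(g in self.mito_genes) for g in self.gene_ids]}
                     ).to_csv(f"{prefix}genes.tsv", sep="\t", index=False)
        pd.DataFrame({"barcode": self.cell_ids}).to_csv(
            f"{prefix}barcodes.tsv", sep="\t", index=False)
        if self.labels is not None:
            pd.DataFrame({"barcode": self.cell_ids, "label": self.labels}
                         ).to_csv(f"{prefix}labels.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, prefix: str) -> "CellMatrix":
        counts = sp.csr_matrix(mmread(f"{prefix}matrix.mtx"))
        genes = pd.read_csv(f"{prefix}genes.tsv", sep="\t")
        barcodes = pd.read_csv(f"{prefix}barcodes.tsv", sep="\t")
        labels = None
        try:
            lab = pd.read_csv(f"{prefix}labels.tsv", sep="\t")
            labels = lab["label"].to_numpy(dtype=object)
        except FileNotFoundError:
            pass
        mito = frozenset(genes.loc[genes.get("mito", 0) == 1, "gene"])
        return cls(counts=counts,
                   gene_ids=genes["gene"].to_numpy(dtype=object),
                   cell_ids=barcodes["barcode"].to_numpy(dtype=object),
                   labels=labels, mito_genes=mito)


@dataclass
class ReferenceProfiles:
    """Genes x cell-type matrix of expression frequencies.

    Each column is the count frequency profile of one reference cell type
    and sums to one. ``lineage_tags`` maps each type name to a coarse
    lineage ("lymphoid", "myeloid", "progenitor", ...). ``gene_weights``
    are the optional non-negative weights applied per gene in the
    deconvolution objective (default 1 everywhere).
    """

    profile: np.ndarray
    gene_ids: np.ndarray
    cell_type_names: list
    lineage_tags: dict = field(default_factory=dict)
    gene_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_type_names = list(self.cell_type_names)
        if self.profile.shape != (len(self.gene_ids), len(self.cell_type_names)):
            raise ValueError("profile shape does not match gene/type names")
        if (self.profile < 0).any():
            raise ValueError("profiles must be non-negative")
        colsums = self.profile.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("profile columns must each sum to 1")
        if self.gene_weights is None:
            self.gene_weights = np.ones(len(self.gene_ids))
        self.gene_weights = np.asarray(self.gene_weights, dtype=float)
        if (self.gene_weights < 0).any():
            raise ValueError("gene_weights must be non-negative")
        if len(self.gene_weights) != len(self.gene_ids):
            raise ValueError("gene_weights must align with gene_ids")

    @property
    def n_types(self) -> int:
        return len(self.cell_type_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profile, index=self.gene_ids,
                            columns=self.cell_type_names)

    def write(self, path: str, meta_path: str | None = None) -> None:
        self.to_frame().rename_axis("gene").to_csv(path, sep="\t")
        if meta_path is not None:
            import json
            with open(meta_path, "w") as fh:
                json.dump({"lineage_tags": self.lineage_tags,
                           "cell_types": self.cell_type_names}, fh, indent=2)

    @classmethod
    def read(cls, path: str, meta_path: str | None = None,
             weights_path: str | None = None) -> "ReferenceProfiles":
        df = pd.read_csv(path, sep="\t", index_col=0)
        tags = {}
        if meta_path is not None:
            import json
            with open(meta_path) as fh:
                tags = json.load(fh).get("lineage_tags", {})
        weights = None
        if weights_path is not None:
            wdf = pd.read_csv(weights_path, sep="\t", index_col=0)
            weights = wdf.iloc[:, 0].reindex(df.index).fillna(1.0).to_numpy()
        return cls(profile=df.to_numpy(), gene_ids=df.index.to_numpy(dtype=object),
                   cell_type_names=list(df.columns), lineage_tags=tags,
                   gene_weights=weights)
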
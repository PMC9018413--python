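"""Regularized logistic matching of query cells to reference cell types.

A one-vs-rest elastic-net logistic model (mixing parameter alpha = 0.99,
i.e. lasso-dominant, giving strong regularization and sparse
coefficients) is trained per reference type on log-normalized expression.
Query cells receive an independent sigmoid probability per type — scores
need not sum to one across types, so a cell may match nothing. Per-cell
calls use strict similarity bands: p > hi is "similar", p < lo is
"dissimilar", the rest "intermediate".
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV

from .containers import CellMatrix

__all__ = ["MatchModel", "train_matcher", "predict_similarity",
           "summarize_clusters", "call_cells", "assign_cancer_clusters"]

logger = logging.getLogger(__name__)


@dataclass
class MatchModel:
    """Per-type logistic scorers over a fixed gene universe."""

    gene_ids: np.ndarray
    class_names: list
    coef: np.ndarray          # n_types x n_genes
    intercept: np.ndarray     # n_types
    alpha: float
    folds: int
    chosen_C: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.coef.shape != (len(self.class_names), len(self.gene_ids)):
            raise ValueError("coefficient matrix shape mismatch")

    def sparsity(self) -> pd.Series:
        """Fraction of exactly-zero coefficients per type."""
        return pd.Series((self.coef == 0).mean(axis=1), index=self.class_names)

    def save(self, coef_path: str, meta_path: str) -> None:
        rows = []
        for k, name in enumerate(self.class_names):
            nz = np.flatnonzero(self.coef[k])
            for j in nz:
                rows.append((name, self.gene_ids[j], self.coef[k, j]))
        pd.DataFrame(rows, columns=["cell_type", "gene", "coef"]).to_csv(
            coef_path, sep="\t", index=False)
        with open(meta_path, "w") as fh:
            json.dump({"class_names": self.class_names,
                       "gene_ids": list(map(str, self.gene_ids)),
                       "intercept": self.intercept.tolist(),
                       "alpha": self.alpha, "folds": self.folds,
                       "chosen_C": {k: float(v) for k, v in self.chosen_C.items()},
                       "seed": self.seed}, fh)

    @classmethod
    def load(cls, coef_path: str, meta_path: str) -> "MatchModel":
        with open(meta_path) as fh:
            meta = json.load(fh)
        gene_ids = np.array(meta["gene_ids"], dtype=object)
        gidx = {g: j for j, g in enumerate(gene_ids)}
        coef = np.zeros((len(meta["class_names"]), len(gene_ids)))
        tab = pd.read_csv(coef_path, sep="\t")
        cidx = {c: k for k, c in enumerate(meta["class_names"])}
        for _, row in tab.iterrows():
            coef[cidx[row["cell_type"]], gidx[str(row["gene"])]] = row["coef"]
        return cls(gene_ids=gene_ids, class_names=meta["class_names"],
                   coef=coef, intercept=np.array(meta["intercept"]),
                   alpha=meta["alpha"], folds=meta["folds"],
                   chosen_C=meta["chosen_C"], seed=meta["seed"])


def _penalty_path(X, y, w, l1_ratio: float, n_lambdas: int,
                  decades: float = 2.0) -> np.ndarray:
    """Logarithmic grid of inverse penalties (sklearn ``C``) spanning
    ``decades`` below the edge at which every coefficient is exactly
    zero — the glmnet-style path, which keeps the search inside the
    sparse regime instead of drifting to unpenalized fits."""
    ybar = np.average(y, weights=w)
    score = np.abs(X.T @ (w * (y - ybar)))
    edge = l1_ratio / max(float(np.max(score)), 1e-12)
    return np.logspace(np.log10(edge), np.log10(edge) + decades, n_lambdas)


def train_matcher(ref_cells: CellMatrix, alpha: float = 0.99, folds: int = 10,
                  n_lambdas: int = 20, seed: int = 0,
                  max_iter: int = 500) -> MatchModel:
    """Train one-vs-rest elastic-net logistic scorers on labeled,
    log-normalized reference cells.

    The penalty strength is chosen per type by cross-validated deviance
    (log loss) over a logarithmic grid of ``n_lambdas`` values spanning
    two decades below the all-zero-coefficient edge, picking the minimum
    (no one-standard-error rule). Class imbalance is handled by
    inverse-frequency observation weights. Deterministic given ``seed``.
    """
    if ref_cells.labels is None:
        raise ValueError("training requires cell-type labels")
    classes = sorted(set(ref_cells.labels))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 cell types")
    labels = np.asarray(ref_cells.labels)
    counts = pd.Series(labels).value_counts()
    small = counts[counts < folds]
    if len(small):
        raise ValueError(
            f"types with fewer cells than folds={folds}: "
            f"{dict(small)}; reduce the number of folds")
    X = ref_cells.counts.T.tocsr()  # cells x genes
    coef = np.zeros((len(classes), ref_cells.n_genes))
    intercept = np.zeros(len(classes))
    chosen = {}
    for k, cls_name in enumerate(classes):
        y = (labels == cls_name).astype(int)
        # inverse-frequency weights balance the one-vs-rest contrast
        w = np.where(y == 1, 0.5 / y.mean(), 0.5 / (1 - y.mean()))
        Cs = _penalty_path(X, y, w, alpha, n_lambdas)
        model = LogisticRegressionCV(
            Cs=Cs, cv=folds, l1_ratios=[alpha], solver="saga",
            scoring="neg_log_loss", max_iter=max_iter,
            random_state=seed, n_jobs=1, tol=1e-3)
        with warnings.catch_warnings():
            # scikit-learn attribute-layout deprecation chatter; harmless
            warnings.simplefilter("ignore", FutureWarning)
            warnings.simplefilter("ignore", UserWarning)
            model.fit(X, y, sample_weight=w)
        coef[k] = model.coef_[0]
        # balancing recenters the implicit base rate at 1/2; shift the
        # intercept back to the true class prevalence (case-control prior
        # correction) so "matches nothing" cells score below chance
        prev = y.mean()
        intercept[k] = model.intercept_[0] + np.log(prev / (1 - prev))
        chosen[cls_name] = float(model.C_[0])
    return MatchModel(gene_ids=ref_cells.gene_ids, class_names=classes,
                      coef=coef, intercept=intercept, alpha=alpha,
                      folds=folds, chosen_C=chosen, seed=seed)


def predict_similarity(model: MatchModel, query: CellMatrix) -> pd.DataFrame:
    """Per-cell, per-type sigmoid similarity probabilities.

    Query genes are aligned to the model's universe by id; genes the model
    knows but the query lacks are imputed as zero (logged). Probabilities
    do not sum to 1 across types (one-vs-rest contract).
    """
    if query.n_cells == 0:
        raise ValueError("empty query matrix")
    gidx = {g: j for j, g in enumerate(model.gene_ids)}
    Xq = np.zeros((query.n_cells, len(model.gene_ids)))
    present = 0
    dense = query.counts.T.toarray()
    for i, g in enumerate(query.gene_ids):
        j = gidx.get(g)
        if j is not None:
            Xq[:, j] = dense[:, i]
            present += 1
    missing = len(model.gene_ids) - present
    if missing:
        logger.info("predict_similarity: %d model genes absent from query, "
                    "imputed as 0", missing)
    z = Xq @ model.coef.T + model.intercept
    prob = 1.0 / (1.0 + np.exp(-z))
    return pd.DataFrame(prob, index=query.cell_ids, columns=model.class_names)


def summarize_clusters(calls: pd.DataFrame, cluster_labels) -> pd.DataFrame:
    """Mean match probability per cluster x reference type."""
    lab = pd.Series(np.asarray(cluster_labels, dtype=object), index=calls.index)
    if lab.isna().any():
        raise ValueError("cluster labels must cover all cells")
    return calls.groupby(lab).mean()


def call_cells(calls: pd.DataFrame, hi: float = 0.8,
               lo: float = 0.2) -> pd.DataFrame:
    """Per type, fractions of cells strictly above/below the similarity
    bands (p > hi similar, p < lo dissimilar, rest intermediate)."""
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("need 0 <= lo < hi <= 1")
    similar = (calls > hi).mean(axis=0)
    dissimilar = (calls < lo).mean(axis=0)
    return pd.DataFrame({"similar": similar,
                         "intermediate": 1.0 - similar - dissimilar,
                         "dissimilar": dissimilar})


def assign_cancer_clusters(cells: CellMatrix, cluster_labels,
                           positive_panel, normal_panels: dict,
                           expr_threshold: float = 0.5,
                           panel_share: float = 0.5) -> pd.Series:
    """Label clusters cancer/noncancer from immunophenotype panels.

    A cluster is cancer iff at least ``panel_share`` of the positive-panel
    genes have cluster-mean normalized expression above ``expr_threshold``
    AND no normal lineage panel reaches that share. Panel genes absent
    from the matrix are warned about and excluded.
    """
    import warnings

    if not positive_panel or not normal_panels:
        raise ValueError("panels must be nonempty")
    lab = np.asarray(cluster_labels, dtype=object)
    if len(lab) != cells.n_cells:
        raise ValueError("cluster labels must cover all cells")
    gidx = {g: j for j, g in enumerate(cells.gene_ids)}

    def _present(panel, name):
        found = [g for g in panel if g in gidx]
        absent = sorted(set(panel) - set(found))
        if absent:
            warnings.warn(f"panel {name!r}: genes absent from matrix "
                          f"excluded: {absent}", stacklevel=3)
        if not found:
            raise ValueError(f"panel {name!r} has no genes in the matrix")
        return found

    pos = _present(positive_panel, "positive")
    normals = {k: _present(v, k) for k, v in normal_panels.items()}
    dense = cells.counts.toarray()
    out = {}
    for cl in sorted(set(lab)):
        mean_expr = dense[:, lab == cl].mean(axis=1)

        def share(panel):
            vals = np.array([mean_expr[gidx[g]] for g in panel])
            return float((vals > expr_threshold).mean())

        is_cancer = (share(pos) >= panel_share and
                     all(share(p) < panel_share for p in normals.values()))
        out[cl] = "cancer" if is_cancer else "noncancer"
    return pd.Series(out)
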
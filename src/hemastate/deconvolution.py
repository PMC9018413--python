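"""Bulk transcriptome deconvolution against a single-cell reference.

Each bulk count vector is modeled as a Poisson draw from a non-negative
mixture of reference cell-type frequency profiles plus a flat "intercept"
profile that absorbs signal unexplained by any reference type:

    b_g ~ Poisson( N * ( sum_k f_k p_gk + f0 / G ) ),  f >= 0

maximized as the weighted log-likelihood sum_g w_g (b_g log lam_g - lam_g)
by multiplicative updates with the basis fixed. Reported fractions are
normalized so reference weights plus the intercept sum to one. The module
also provides the ELP-to-later-B ratio statistic and the classical
two-group comparisons used to contrast leukemia subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._optim import fit_fixed_basis_poisson
from .containers import ReferenceProfiles

__all__ = ["ExposureVector", "GroupComparison", "fit_exposures",
           "deconvolve_cohort", "elp_ratio", "compare_groups",
           "LATER_B_TYPES"]

#: Later B-cell developmental stages whose summed signal forms the
#: denominator of the ELP ratio.
LATER_B_TYPES = ("pre-pro-B", "pro-B", "pre-B", "naive-B")

MIN_SHARED_GENES = 500


@dataclass
class ExposureVector:
    """Fitted cell-signal fractions for one bulk sample.

    ``fractions`` maps reference type name -> weight; ``intercept`` is the
    unexplained weight. Together they sum to 1.
    """

    fractions: dict
    intercept: float
    loglik: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        vals = np.array(list(self.fractions.values()) + [self.intercept])
        if (vals < 0).any():
            raise ValueError("fractions and intercept must be non-negative")
        if not np.isclose(vals.sum(), 1.0, atol=1e-6):
            raise ValueError("fractions + intercept must sum to 1")

    def as_series(self) -> pd.Series:
        s = pd.Series(self.fractions, dtype=float)
        s["intercept"] = self.intercept
        return s


@dataclass
class GroupComparison:
    statistic_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def fit_exposures(bulk, ref: ReferenceProfiles, bulk_gene_ids=None,
                  tol: float = 1e-8, max_iter: int = 10_000,
                  min_shared_genes: int = MIN_SHARED_GENES) -> ExposureVector:
    """Fit one bulk count vector as reference mixture + flat intercept.

    ``bulk`` is a vector of non-negative integer counts, aligned to
    ``ref.gene_ids`` unless ``bulk_gene_ids`` is given, in which case the
    two gene universes are intersected by id (requiring at least
    ``min_shared_genes`` in common). Deterministic: equal-weight
    initialization, no randomness.
    """
    bulk = np.asarray(bulk)
    if bulk.ndim != 1:
        raise ValueError("bulk must be a 1-D count vector")
    if (bulk < 0).any():
        raise ValueError("bulk counts must be non-negative")
    if not np.allclose(bulk, np.round(bulk)):
        raise ValueError("bulk counts must be integers")
    bulk = bulk.astype(float)

    if bulk_gene_ids is None:
        if len(bulk) != len(ref.gene_ids):
            raise ValueError("bulk length does not match reference genes; "
                             "pass bulk_gene_ids to intersect")
        profile, weights = ref.profile, ref.gene_weights
    else:
        bulk_gene_ids = np.asarray(bulk_gene_ids, dtype=object)
        ref_index = {g: i for i, g in enumerate(ref.gene_ids)}
        keep_b, keep_r = [], []
        for i, g in enumerate(bulk_gene_ids):
            j = ref_index.get(g)
            if j is not None:
                keep_b.append(i)
                keep_r.append(j)
        if len(keep_b) < min_shared_genes:
            raise ValueError(
                f"only {len(keep_b)} genes shared between bulk and reference "
                f"(need >= {min_shared_genes})")
        bulk = bulk[keep_b]
        profile = ref.profile[keep_r, :]
        # re-normalize columns after intersection so each remains a profile
        profile = profile / np.maximum(profile.sum(axis=0), 1e-300)
        weights = ref.gene_weights[keep_r]

    G = len(bulk)
    basis = np.column_stack([profile, np.full(G, 1.0 / G)])
    fit = fit_fixed_basis_poisson(bulk, basis, weights=weights,
                                  tol=tol, max_iter=max_iter)
    frac = fit.fractions
    return ExposureVector(
        fractions={t: float(frac[k]) for k, t in enumerate(ref.cell_type_names)},
        intercept=float(frac[-1]), loglik=fit.loglik,
        n_iter=fit.n_iter, converged=fit.converged)


def deconvolve_cohort(bulks: pd.DataFrame, ref: ReferenceProfiles,
                      subtypes: dict | pd.Series | None = None,
                      **fit_kwargs):
    """Deconvolve a gene x sample count table and summarize by subtype.

    Returns ``(exposure_table, subtype_means)``: per-sample exposures
    (rows = samples; columns = types, intercept, loglik, converged) and
    per-subtype mean signals. Subtypes represented by a single sample are
    excluded from the mean table.
    """
    if bulks.shape[1] < 1:
        raise ValueError("need at least one bulk sample")
    gene_ids = bulks.index.to_numpy(dtype=object)
    rows = {}
    for sample in bulks.columns:
        e = fit_exposures(bulks[sample].to_numpy(), ref,
                          bulk_gene_ids=gene_ids, **fit_kwargs)
        s = e.as_series()
        s["loglik"] = e.loglik
        s["converged"] = float(e.converged)
        rows[sample] = s
    table = pd.DataFrame(rows).T
    means = None
    if subtypes is not None:
        sub = pd.Series(subtypes).reindex(table.index)
        sizes = sub.value_counts()
        keep = sizes[sizes >= 2].index
        signal_cols = list(ref.cell_type_names) + ["intercept"]
        means = (table.loc[sub.isin(keep), signal_cols]
                 .groupby(sub[sub.isin(keep)]).mean())
    return table, means


def elp_ratio(exposure: ExposureVector, elp_type: str = "ELP",
              later_b_types=LATER_B_TYPES, eps: float = 1e-6) -> float:
    """(f_ELP + eps) / (sum of later-B-stage signals + eps).

    The pseudocount keeps the ratio finite when later-B signals vanish.
    """
    if elp_type not in exposure.fractions:
        raise KeyError(f"reference has no type named {elp_type!r}")
    missing = [t for t in later_b_types if t not in exposure.fractions]
    if missing:
        raise KeyError(f"reference lacks later-B types: {missing}")
    later = sum(exposure.fractions[t] for t in later_b_types)
    return (exposure.fractions[elp_type] + eps) / (later + eps)


def compare_groups(values_a, values_b, test: str = "t",
                   paired: bool = False) -> GroupComparison:
    """Two-group comparison: Welch t (two-tailed), Mann-Whitney U
    (two-sided, normal approximation with tie correction) or Wilcoxon
    signed-rank (two-sided, paired)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test in ("wilcoxon", "signed-rank") or (paired and test == "wilcoxon"):
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length groups")
        d = a - b
        if np.all(d == 0):
            raise ValueError("all paired differences are zero; "
                             "signed-rank test undefined")
        res = stats.wilcoxon(a, b, zero_method="wilcox", mode="auto")
        name = "wilcoxon-signed-rank"
    elif test in ("mannwhitney", "mann-whitney", "u"):
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        name = "mann-whitney"
    elif test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
        name = "welch-t"
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(statistic_name=name, statistic=float(res.statistic),
                           p_value=float(res.pvalue), n_a=len(a), n_b=len(b))
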
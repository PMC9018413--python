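"""Core cancer transcriptome derivation and annotation.

The cross-validated "core transcriptome" is the overlap of two
independent differential-expression contrasts of leukemia against its
closest normal correlate. This module provides the pieces: pseudobulk
aggregation of single cells, a negative-binomial Wald test on pseudobulk
replicates, gene-set overlap, a Monte Carlo enrichment test against a
known target-gene catalog, lineage-specificity tagging of genes in the
normal reference, and coexpression scoring of cross-lineage
surface-marker pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CellMatrix

__all__ = ["pseudobulk", "de_nb_wald", "core_overlap", "mc_enrichment",
           "lineage_specificity", "pair_coexpression", "build_marker_pairs",
           "EnrichmentResult"]

logger = logging.getLogger(__name__)


def pseudobulk(cells: CellMatrix, grouping) -> pd.DataFrame:
    """Sum raw counts per group; returns a gene x group table."""
    lab = np.asarray(grouping, dtype=object)
    if len(lab) != cells.n_cells:
        raise ValueError("grouping must cover all cells")
    counts = cells.counts.tocsc()
    out = {}
    for g in dict.fromkeys(lab):
        idx = np.flatnonzero(lab == g)
        if len(idx) == 0:
            raise ValueError(f"empty group {g!r}")
        out[g] = counts[:, idx].sum(axis=1).A1
    return pd.DataFrame(out, index=cells.gene_ids)


# --------------------------------------------------------------------------
# Negative-binomial Wald differential expression
# --------------------------------------------------------------------------

def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (library-size fallback when no gene
    is expressed in every sample)."""
    allpos = (counts > 0).all(axis=1)
    if allpos.sum() < 10:
        lib = counts.sum(axis=0)
        return lib / np.exp(np.mean(np.log(lib)))
    logc = np.log(counts[allpos])
    ratios = logc - logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(ratios, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def _dispersion_estimates(counts, sf, groups):
    """Per-gene NB dispersion: method-of-moments within groups, shrunk on
    the log scale toward a fitted mean-dispersion trend a0/mu + a1."""
    norm = counts / sf[None, :]
    mu = np.zeros_like(norm)
    for g in np.unique(groups):
        j = groups == g
        mu[:, j] = norm[:, j].mean(axis=1, keepdims=True)
    n, p = counts.shape[1], 2
    resid_var = ((norm - mu) ** 2).sum(axis=1) / (n - p)
    base_mu = np.maximum(norm.mean(axis=1), 1e-8)
    raw = (resid_var - base_mu) / base_mu ** 2
    raw = np.clip(raw, 1e-4, 10.0)
    # parametric trend alpha(mu) = a1 + a0/mu, fitted by least squares on
    # moderately expressed genes
    ok = base_mu > 1
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / base_mu[ok]])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        a1, a0 = max(coef[0], 1e-4), max(coef[1], 0.0)
    else:
        a1, a0 = np.median(raw), 0.0
    trend = np.clip(a1 + a0 / base_mu, 1e-4, 10.0)
    # geometric shrinkage toward the trend stabilizes few-replicate MoM
    w = 0.6
    return np.exp((1 - w) * np.log(raw) + w * np.log(trend))


def de_nb_wald(counts: pd.DataFrame, group_a, group_b,
               padj_cut: float = 0.05, lfc_cut: float = 1.0) -> pd.DataFrame:
    """Negative-binomial Wald test between two pseudobulk groups.

    ``counts`` is a gene x sample table; ``group_a``/``group_b`` name its
    columns (>= 2 replicates each). Per gene: median-of-ratios size
    factors, moment dispersion shrunk toward a mean-dispersion trend, an
    NB GLM with a group indicator, and a Wald test on the log2 fold
    change. Returns per-gene log2FC (B vs A), raw and BH-adjusted p,
    group means, and a significance flag (padj < ``padj_cut`` and
    absolute log2FC > ``lfc_cut``). Genes with zero counts everywhere are
    reported NA and excluded from testing.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    cols = group_a + group_b
    mat = counts[cols].to_numpy(dtype=float)
    design = np.array([0] * len(group_a) + [1] * len(group_b))
    sf = _size_factors(mat)
    nonzero = mat.sum(axis=1) > 0
    alpha = np.full(mat.shape[0], np.nan)
    alpha[nonzero] = _dispersion_estimates(mat[nonzero], sf, design)
    X = sm.add_constant(design.astype(float))
    offset = np.log(sf)
    lfc = np.full(mat.shape[0], np.nan)
    pval = np.full(mat.shape[0], np.nan)
    for i in np.flatnonzero(nonzero):
        fam = sm.families.NegativeBinomial(alpha=float(alpha[i]))
        try:
            res = sm.GLM(mat[i], X, family=fam, offset=offset).fit(maxiter=100)
            beta = res.params[1]
            se = res.bse[1]
            if not np.isfinite(se) or se <= 0:
                continue
            lfc[i] = beta / np.log(2)
            # t reference with residual df is a small-sample correction to
            # the asymptotic Wald normal (dispersions are estimated)
            pval[i] = 2 * stats.t.sf(abs(beta / se), df=len(cols) - 2)
        except Exception:  # rare separation/convergence failures stay NA
            continue
    padj = np.full(mat.shape[0], np.nan)
    tested = np.isfinite(pval)
    if tested.any():
        padj[tested] = multipletests(pval[tested], method="fdr_bh")[1]
    norm = mat / sf[None, :]
    out = pd.DataFrame({
        "log2fc": lfc, "pvalue": pval, "padj": padj,
        "mean_a": norm[:, design == 0].mean(axis=1),
        "mean_b": norm[:, design == 1].mean(axis=1),
    }, index=counts.index)
    out["significant"] = (out["padj"] < padj_cut) & (out["log2fc"].abs() > lfc_cut)
    out.loc[~tested, "significant"] = False
    return out


def core_overlap(list_a, list_b) -> list:
    """Exact id intersection of two DE gene lists (order of ``list_a``)."""
    if not len(list_a) or not len(list_b):
        raise ValueError("gene lists must be nonempty")
    set_b = set(list_b)
    return [g for g in dict.fromkeys(list_a) if g in set_b]


@dataclass
class EnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    p_empirical: float
    p_t: float
    p_hypergeom: float
    reps: int


def mc_enrichment(core_size: int, target_set_size: int, observed_overlap: int,
                  universe_size: int = 33_660, reps: int = 1000,
                  seed: int = 0) -> EnrichmentResult:
    """Monte Carlo enrichment of a target gene set within a core set.

    Draws ``core_size`` genes from the universe without replacement
    ``reps`` times and counts overlap with the target set. Reports the
    empirical tail p = (1 + #{null >= observed}) / (reps + 1), a
    t-statistic p comparing the observed overlap to the null sample, and
    the exact hypergeometric tail as a cross-check.
    """
    if observed_overlap > core_size:
        raise ValueError("observed overlap cannot exceed the core size")
    if target_set_size > universe_size or core_size > universe_size:
        raise ValueError("set sizes cannot exceed the universe")
    rng = np.random.default_rng(seed)
    # overlap of a uniform draw of core_size genes with the target set is
    # exactly hypergeometric; sampled without replacement
    null = rng.hypergeometric(target_set_size,
                              universe_size - target_set_size,
                              core_size, size=reps)
    p_emp = (1 + int((null >= observed_overlap).sum())) / (reps + 1)
    sd = float(null.std(ddof=1))
    tstat = (observed_overlap - null.mean()) / sd if sd > 0 else np.inf
    p_t = float(stats.t.sf(tstat, df=reps - 1))
    p_hyp = float(stats.hypergeom.sf(observed_overlap - 1, universe_size,
                                     target_set_size, core_size))
    return EnrichmentResult(observed=observed_overlap,
                            null_mean=float(null.mean()), null_sd=sd,
                            p_empirical=p_emp, p_t=p_t, p_hypergeom=p_hyp,
                            reps=reps)


def lineage_specificity(ref_cells: CellMatrix, genes, lineage_tags: dict,
                        on_frac: float = 0.25, off_frac: float = 0.05,
                        ) -> pd.Series:
    """Tag genes lymphoid/myeloid/etc. by expression restriction.

    A gene is tagged to a lineage iff it is expressed (normalized count
    > 0) in at least ``on_frac`` of cells of some type in that lineage
    and in at most ``off_frac`` of cells of every type outside it. Genes
    meeting the on-criterion in several lineages are "shared"; genes
    absent from the matrix or expressed nowhere are "none".
    """
    import warnings

    if ref_cells.labels is None:
        raise ValueError("reference cells must carry type labels")
    labels = np.asarray(ref_cells.labels)
    types = sorted(set(labels))
    lineages = {}
    for t in types:
        lineages.setdefault(lineage_tags.get(t, "other"), []).append(t)
    gidx = {g: j for j, g in enumerate(ref_cells.gene_ids)}
    dense = ref_cells.counts.toarray()
    expr_frac = pd.DataFrame(
        {t: (dense[:, labels == t] > 0).mean(axis=1) for t in types},
        index=ref_cells.gene_ids)
    out = {}
    for g in genes:
        if g not in gidx:
            warnings.warn(f"gene {g!r} absent from reference", stacklevel=2)
            out[g] = "none"
            continue
        frac = expr_frac.loc[g]
        on_lineages = []
        for lin, members in lineages.items():
            on = any(frac[t] >= on_frac for t in members)
            off_ok = all(frac[t] <= off_frac
                         for l2, mem2 in lineages.items() if l2 != lin
                         for t in mem2)
            if on and off_ok:
                on_lineages.append(lin)
        if len(on_lineages) == 1:
            out[g] = on_lineages[0]
        elif any(any(frac[t] >= on_frac for t in mem)
                 for mem in lineages.values()):
            out[g] = "shared" if not on_lineages else on_lineages[0]
        else:
            out[g] = "none"
    return pd.Series(out, name="lineage")


def build_marker_pairs(myeloid_markers, lymphoid_markers) -> list:
    """Full cross of myeloid x lymphoid surface markers (the candidate
    nonphysiological combinations)."""
    return list(itertools.product(myeloid_markers, lymphoid_markers))


def pair_coexpression(cells: CellMatrix, cluster_labels, pairs,
                      ) -> pd.DataFrame:
    """Coexpression scores per cluster x marker pair.

    ``cells`` holds normalized log expression. For each pair, the level
    is the mean over cells of the product of the two genes' values; the
    fraction is the share of cells with both genes > 0. Pairs with a
    missing gene are skipped with a log message.
    """
    lab = np.asarray(cluster_labels, dtype=object)
    if len(lab) != cells.n_cells:
        raise ValueError("cluster labels must cover all cells")
    gidx = {g: j for j, g in enumerate(cells.gene_ids)}
    dense = cells.counts.toarray()
    rows = []
    for ga, gb in pairs:
        if ga not in gidx or gb not in gidx:
            logger.warning("pair (%s, %s) skipped: gene missing", ga, gb)
            continue
        xa, xb = dense[gidx[ga]], dense[gidx[gb]]
        for cl in dict.fromkeys(lab):
            m = lab == cl
            level = float((xa[m] * xb[m]).mean())
            frac = float(((xa[m] > 0) & (xb[m] > 0)).mean())
            rows.append((cl, ga, gb, level, frac))
    return pd.DataFrame(rows, columns=["cluster", "gene_a", "gene_b",
                                       "level", "fraction"])
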
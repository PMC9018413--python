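"""Somatic phylogeny of a remission/ALL/AML trio from variant read counts.

Given per-variant, per-sample alt/total read counts, the module:

1. removes germline variants with a one-sided exact binomial test of the
   observed counts against heterozygous expectation (VAF 0.5 on diploid
   autosomes, 0.95 on X/Y in XY cases), Benjamini-Hochberg corrected;
2. removes sites of consistently aberrant coverage (mean depth outside
   20-60 on autosomes, 10-30 on X/Y);
3. removes recurrent low-level artifact sites with a beta-binomial model
   of site-specific error: sites whose counts across samples are well fit
   by a single binomial rate (low overdispersion rho) are noise, whereas
   true somatic variants present in a subset of samples are strongly
   overdispersed;
4. assigns retained variants to phylogenetic branches from their
   presence pattern across the trio (all three = early embryonic;
   both tumors only = leukemia-common; one tumor = that tumor's private
   branch);
5. classifies tumor variants clonal/subclonal with a binomial mixture
   model fitted by EM, the number of components chosen by BIC, clonality
   judged against the purity-adjusted heterozygous VAF;
6. converts a branch's substitution count into an upper bound on the
   number of cell divisions elapsed, using a minimum mutation rate per
   division.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = ["VariantTable", "Phylogeny", "MixtureFit",
           "germline_filter", "depth_filter", "site_error_model",
           "assign_branches", "fit_clonality_mixture", "time_origin",
           "expected_clonal_vaf"]

_ACCEPTED_CHROMS = tuple(str(c) for c in range(1, 23)) + ("X", "Y")


def _norm_chrom(c: str) -> str:
    c = str(c)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c not in _ACCEPTED_CHROMS:
        raise ValueError(
            f"unknown chromosome {c!r}; accepted names: "
            f"{', '.join(_ACCEPTED_CHROMS)} (optionally 'chr'-prefixed)")
    return c


@dataclass
class VariantTable:
    """Wide-format multi-sample variant read counts with filter flags.

    ``alt_reads`` / ``total_reads`` are variants x samples integer arrays;
    ``meta`` holds chrom/pos/ref/alt (one row per variant); ``flags``
    accumulates boolean columns (germline, depth_fail, artifact, absent)
    as the filters run; ``branch`` is filled by ``assign_branches``.
    """

    meta: pd.DataFrame
    samples: list
    alt_reads: np.ndarray
    total_reads: np.ndarray
    flags: pd.DataFrame = None
    branch: pd.Series = None

    def __post_init__(self) -> None:
        self.alt_reads = np.asarray(self.alt_reads, dtype=int)
        self.total_reads = np.asarray(self.total_reads, dtype=int)
        n = len(self.meta)
        if self.alt_reads.shape != (n, len(self.samples)):
            raise ValueError("alt_reads shape mismatch")
        if self.total_reads.shape != self.alt_reads.shape:
            raise ValueError("total_reads shape mismatch")
        if (self.alt_reads < 0).any() or (self.alt_reads > self.total_reads).any():
            raise ValueError("need 0 <= alt_reads <= total_reads")
        if (self.meta["pos"] < 1).any():
            raise ValueError("positions are 1-based; pos >= 1 required")
        self.meta = self.meta.reset_index(drop=True)
        self.meta["chrom"] = [_norm_chrom(c) for c in self.meta["chrom"]]
        if self.flags is None:
            self.flags = pd.DataFrame(index=self.meta.index)

    @property
    def n_variants(self) -> int:
        return len(self.meta)

    def is_sex_chrom(self) -> np.ndarray:
        return self.meta["chrom"].isin(["X", "Y"]).to_numpy()

    @classmethod
    def from_long(cls, df: pd.DataFrame,
                  truth_col: str | None = "truth_class") -> "VariantTable":
        """Build from a long table with columns chrom, pos, ref, alt,
        sample, alt_reads, total_reads (the generator/TSV layout)."""
        key = ["chrom", "pos", "ref", "alt"]
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        samples = list(dict.fromkeys(df["sample"]))
        alt_w = df.pivot_table(index=key, columns="sample", values="alt_reads",
                               sort=False)[samples]
        dep_w = df.pivot_table(index=key, columns="sample", values="total_reads",
                               sort=False)[samples]
        meta = alt_w.index.to_frame(index=False)
        vt = cls(meta=meta, samples=samples,
                 alt_reads=alt_w.to_numpy(), total_reads=dep_w.to_numpy())
        if truth_col is not None and truth_col in df.columns:
            truth = df.drop_duplicates(key).set_index(key)[truth_col]
            vt.meta[truth_col] = truth.loc[
                list(alt_w.index)].to_numpy()
        return vt

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_variants):
            for j, s in enumerate(self.samples):
                rows.append((*self.meta.loc[i, ["chrom", "pos", "ref", "alt"]],
                             s, self.alt_reads[i, j], self.total_reads[i, j]))
        out = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                          "sample", "alt_reads", "total_reads"])
        return out

    def retained(self) -> np.ndarray:
        """Variants passing every filter that has been run so far."""
        keep = np.ones(self.n_variants, dtype=bool)
        for col in ("germline", "depth_fail", "artifact", "absent"):
            if col in self.flags:
                keep &= ~self.flags[col].to_numpy()
        return keep


# --------------------------------------------------------------------------
# Filters
# --------------------------------------------------------------------------

def germline_filter(vt: VariantTable, sex: str = "XX",
                    q_cutoff: float = 1e-5, pool: str = "normal",
                    normal: str | None = None) -> pd.Series:
    """Flag variants whose read counts are consistent with germline
    heterozygosity.

    A one-sided exact binomial test asks whether the alt count is
    significantly *below* the heterozygous expectation (p0 = 0.5 on
    diploid autosomes, 0.95 on X/Y for XY cases): p = P(X <= alt | depth,
    p0). After Benjamini-Hochberg adjustment across variants, q >=
    ``q_cutoff`` flags the variant germline; q < cutoff retains it as a
    somatic candidate.

    ``pool`` selects the counts tested: ``"normal"`` (default) uses the
    normal/remission sample only — somatic variants are absent or mosaic
    there, so the test is well powered even when a variant is clonal in
    every tumor; ``"all"`` pools counts across all samples.
    """
    if sex not in ("XX", "XY"):
        raise ValueError("sex must be 'XX' or 'XY'")
    if pool == "normal":
        if normal is None:
            if "remission" in vt.samples:
                normal = "remission"
            else:
                raise ValueError("pool='normal' requires the normal sample name")
        j = vt.samples.index(normal)
        alt = vt.alt_reads[:, j]
        dep = vt.total_reads[:, j]
    elif pool == "all":
        alt = vt.alt_reads.sum(axis=1)
        dep = vt.total_reads.sum(axis=1)
    else:
        raise ValueError("pool must be 'normal' or 'all'")
    p0 = np.where(vt.is_sex_chrom() & (sex == "XY"), 0.95, 0.5)
    pvals = stats.binom.cdf(alt, np.maximum(dep, 1), p0)
    pvals = np.where(dep > 0, pvals, 1.0)  # no coverage: cannot reject germline
    _rej, qvals, _a, _b = multipletests(pvals, method="fdr_bh")
    germ = pd.Series(qvals >= q_cutoff, index=vt.meta.index, name="germline")
    vt.flags["germline"] = germ
    vt.flags["germline_q"] = qvals
    return germ


def depth_filter(vt: VariantTable, auto_range=(20, 60),
                 sexchrom_range=(10, 30)) -> pd.Series:
    """Flag sites whose mean depth across samples falls outside the
    acceptable coverage band (closed ranges)."""
    mean_dep = vt.total_reads.mean(axis=1)
    sexc = vt.is_sex_chrom()
    lo = np.where(sexc, sexchrom_range[0], auto_range[0])
    hi = np.where(sexc, sexchrom_range[1], auto_range[1])
    fail = (mean_dep < lo) | (mean_dep > hi)
    out = pd.Series(fail, index=vt.meta.index, name="depth_fail")
    vt.flags["depth_fail"] = out
    return out


_RHO_GRID = np.logspace(np.log10(1e-6), np.log10(0.89), 101)


def _betabinom_loglik(alt, dep, mu: float, rho: float) -> float:
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return float(stats.betabinom.logpmf(alt, dep, a, b).sum())


def site_error_model(vt: VariantTable, rho_threshold: float = 0.1,
                     max_error_vaf: float = 0.1,
                     rho_grid: np.ndarray = _RHO_GRID) -> pd.DataFrame:
    """Separate true somatic variants from recurrent low-level noise.

    Per site, the across-sample counts are fit by a beta-binomial with
    mean fixed at the pooled VAF and overdispersion rho maximized on a
    logarithmic grid. Counts generated by a shared error process are
    nearly binomial (rho small -> artifact); genuine somatic variants are
    present in a subset of samples and force a large rho. Because
    site-specific *error* processes are low-level by definition, the
    artifact call additionally requires the pooled VAF to stay at or
    below ``max_error_vaf``: a site supported at a substantial pooled
    VAF in every sample is not recurrent noise even if the fitted
    overdispersion is small. Sites with no alt reads anywhere are
    flagged absent without a fit.
    """
    if len(vt.samples) < 3:
        raise ValueError("site error model needs the full trio of samples")
    n = vt.n_variants
    rho_hat = np.full(n, np.nan)
    artifact = np.zeros(n, dtype=bool)
    absent = np.zeros(n, dtype=bool)
    for i in range(n):
        alt = vt.alt_reads[i]
        dep = vt.total_reads[i]
        if alt.sum() == 0:
            absent[i] = True
            continue
        mu = np.clip(alt.sum() / max(dep.sum(), 1), 1e-6, 1 - 1e-6)
        lls = np.array([_betabinom_loglik(alt, dep, mu, r) for r in rho_grid])
        rho_hat[i] = rho_grid[int(np.argmax(lls))]
        artifact[i] = (rho_hat[i] < rho_threshold) and (mu <= max_error_vaf)
    vt.flags["artifact"] = artifact
    vt.flags["absent"] = absent
    vt.flags["rho"] = rho_hat
    return vt.flags[["artifact", "absent", "rho"]]


# --------------------------------------------------------------------------
# Branch assignment and timing
# --------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """Branch substitution counts for the fixed remission/ALL/AML topology."""

    branch_counts: dict
    assignments: pd.Series
    n_inconsistent: int
    samples: dict

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.branch_counts.values()):
            raise ValueError("branch counts must be non-negative")

    def newick(self) -> str:
        e = self.branch_counts.get("embryonic", 0)
        c = self.branch_counts.get("leukemia-common", 0)
        a = self.branch_counts.get("ALL-private", 0)
        m = self.branch_counts.get("AML-private", 0)
        return (f"(remission:0,(ALL:{a},AML:{m}):{c}):{e};")


def assign_branches(vt: VariantTable, normal: str = "remission",
                    tumor_all: str = "ALL", tumor_aml: str = "AML",
                    min_alt: int = 3) -> Phylogeny:
    """Assign every retained variant to a phylogenetic branch from its
    presence pattern across the trio.

    Presence in a sample means alt_reads >= ``min_alt`` at a site the
    error model accepted as true somatic. Patterns map: all three ->
    embryonic; both tumors only -> leukemia-common; a single tumor ->
    that tumor's private branch; any pattern containing the remission
    sample but not both tumors -> inconsistent (flagged, not counted).
    """
    expect = {normal, tumor_all, tumor_aml}
    if len(vt.samples) != 3 or set(vt.samples) != expect:
        raise ValueError(f"expected exactly the trio {sorted(expect)}, "
                         f"got {vt.samples}")
    jn = vt.samples.index(normal)
    ja = vt.samples.index(tumor_all)
    jm = vt.samples.index(tumor_aml)
    keep = vt.retained()
    present = vt.alt_reads >= min_alt
    labels = np.full(vt.n_variants, "filtered", dtype=object)
    counts = {"embryonic": 0, "leukemia-common": 0,
              "ALL-private": 0, "AML-private": 0}
    n_inconsistent = 0
    for i in np.flatnonzero(keep):
        pn, pa, pm = present[i, jn], present[i, ja], present[i, jm]
        if pn and pa and pm:
            lab = "embryonic"
        elif pa and pm:
            lab = "leukemia-common"
        elif pa:
            lab = "ALL-private"
        elif pm:
            lab = "AML-private"
        elif not (pn or pa or pm):
            lab = "undetected"
        else:  # remission without both tumors
            lab = "inconsistent"
            n_inconsistent += 1
        labels[i] = lab
        if lab in counts:
            counts[lab] += 1
    assignments = pd.Series(labels, index=vt.meta.index, name="branch")
    vt.branch = assignments
    return Phylogeny(branch_counts=counts, assignments=assignments,
                     n_inconsistent=n_inconsistent,
                     samples={"normal": normal, "ALL": tumor_all,
                              "AML": tumor_aml})


def time_origin(n_branch_subs: int, rate_min: float = 0.9) -> float:
    """Upper bound on cell divisions elapsed along a branch carrying
    ``n_branch_subs`` substitutions at a minimum mutation rate per
    division (default 0.9 substitutions/division)."""
    if n_branch_subs < 0:
        raise ValueError("substitution count must be >= 0")
    if rate_min <= 0:
        raise ValueError("mutation rate must be positive")
    return n_branch_subs / rate_min


# --------------------------------------------------------------------------
# Clonality mixture
# --------------------------------------------------------------------------

def expected_clonal_vaf(purity: float, n_alt_copies: int = 1,
                        tumor_cn: int = 2) -> float:
    """Expected VAF of a clonal variant: purity * m / (purity * CN_tumor
    + 2 * (1 - purity)); purity/2 in the diploid heterozygous case."""
    return purity * n_alt_copies / (purity * tumor_cn + 2 * (1 - purity))


@dataclass
class MixtureFit:
    """Binomial mixture over variant read counts with clonality calls."""

    K: int
    p: np.ndarray
    pi: np.ndarray
    responsibilities: np.ndarray
    loglik: float
    bic: float
    classes: list
    bic_by_k: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-6):
            raise ValueError("mixture weights must sum to 1")
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("binomial probabilities must lie in [0, 1]")


def _em_binomial(alt, dep, p0, max_iter=1000, tol=1e-10):
    """EM for a K-component binomial mixture; returns (p, pi, resp, loglik).
    Log-likelihood is asserted non-decreasing (monotonicity is an EM
    guarantee; a decrease beyond slack is an implementation bug)."""
    n, K = len(alt), len(p0)
    p = np.clip(np.asarray(p0, float), 1e-6, 1 - 1e-6)
    pi = np.full(K, 1.0 / K)
    prev = -np.inf
    log_comb = stats.binom.logpmf(alt, dep, 0.5) - (
        alt * np.log(0.5) + (dep - alt) * np.log(0.5))
    for _ in range(max_iter):
        logp = (log_comb[:, None]
                + alt[:, None] * np.log(p)[None, :]
                + (dep - alt)[:, None] * np.log1p(-p)[None, :]
                + np.log(pi)[None, :])
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        if ll < prev - 1e-8 * max(1.0, abs(prev)):
            raise RuntimeError("EM log-likelihood decreased: internal error")
        resp = np.exp(logp - norm[:, None])
        p = np.clip((resp * alt[:, None]).sum(0) /
                    np.maximum((resp * dep[:, None]).sum(0), 1e-12),
                    1e-6, 1 - 1e-6)
        pi = np.maximum(resp.mean(axis=0), 1e-12)
        pi = pi / pi.sum()
        if abs(ll - prev) <= tol * max(1.0, abs(ll)):
            prev = ll
            break
        prev = ll
    return p, pi, resp, prev


def fit_clonality_mixture(alt_reads, total_reads, purity: float,
                          tumor_cn: int = 2, K_max: int = 5,
                          tol: float = 0.05, seed: int = 0,
                          n_restarts: int = 5) -> MixtureFit:
    """Deconvolve variant counts into binomial VAF components by EM.

    For each K = 1..K_max the mixture is fitted from ``n_restarts`` seeded
    initializations (VAF quantiles plus jitter) and the best-likelihood
    run kept; the returned K minimizes BIC = -2*loglik + (2K-1)*ln(n).
    A component is clonal when its probability is within ``tol`` of the
    purity-adjusted heterozygous VAF, subclonal when below that band.
    """
    alt = np.asarray(alt_reads, dtype=float)
    dep = np.asarray(total_reads, dtype=float)
    n = len(alt)
    if n < K_max:
        raise ValueError("need at least K_max variants")
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    vaf = alt / np.maximum(dep, 1)
    best = None
    bic_by_k = {}
    for K in range(1, K_max + 1):
        best_k = None
        for r in range(n_restarts):
            q = np.quantile(vaf, (np.arange(K) + 0.5) / K)
            init = np.clip(q + rng.normal(0, 0.02 * (r > 0), size=K),
                           1e-4, 1 - 1e-4)
            p, pi, resp, ll = _em_binomial(alt, dep, init)
            if best_k is None or ll > best_k[3]:
                best_k = (p, pi, resp, ll)
        p, pi, resp, ll = best_k
        bic = -2.0 * ll + (2 * K - 1) * np.log(n)
        bic_by_k[K] = bic
        if best is None or bic < best[0]:
            best = (bic, K, p, pi, resp, ll)
    bic, K, p, pi, resp, ll = best
    target = expected_clonal_vaf(purity, tumor_cn=tumor_cn)
    classes = []
    for pk in p:
        if abs(pk - target) <= tol:
            classes.append("clonal")
        elif pk < target - tol:
            classes.append("subclonal")
        else:
            classes.append("superclonal")
    return MixtureFit(K=K, p=p, pi=pi, responsibilities=resp, loglik=ll,
                      bic=bic, classes=classes, bic_by_k=bic_by_k)
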
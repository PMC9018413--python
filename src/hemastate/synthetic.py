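"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be simulated here:

* a labeled single-cell atlas of negative-binomial expression programs,
  including an ELP-like / later-B lineage gradient (``gen_reference_cells``);
* bulk transcriptomes as Poisson draws from known mixtures of those
  programs plus an off-reference "unexplained" component
  (``gen_bulk_mixture``);
* multi-sample somatic variant tables for a remission/ALL/AML trio with
  embryonic, leukemia-common and private branches, germline sites and
  recurrent low-level artifact sites (``gen_variant_table``);
* 96-channel trinucleotide mutation counts drawn from signature mixtures
  (``gen_signature_counts``), together with a synthetic signature catalog.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CellMatrix, ReferenceProfiles

__all__ = [
    "AtlasSpec", "BulkTruth", "PhyloTruth",
    "gen_reference_cells", "gen_bulk_mixture", "gen_variant_table",
    "gen_signature_counts", "synthetic_signature_catalog",
    "random_atlas_spec", "demo_atlas_spec", "offref_program",
    "SBS96_CHANNELS",
]

# Multiples of `depth_mean` assigned to the remission vs each tumor sample.
# The remission sample is simulated deeper so that low-VAF early-embryonic
# mosaic variants are both detectable (alt >= presence threshold) and
# separable from germline heterozygosity by the exact binomial test
# (see docs/methods.md, "Variant-table generator").
_NORMAL_DEPTH_SHARE = 1.8
_TUMOR_DEPTH_SHARE = 0.75


# --------------------------------------------------------------------------
# Atlas
# --------------------------------------------------------------------------

@dataclass
class AtlasSpec:
    """Recipe for a labeled single-cell atlas.

    ``cell_types`` is a list of ``(name, lineage_tag, n_cells)``.
    ``program_means`` is a types x genes array of non-negative mean
    expression rates (relative; each row is renormalized to a frequency
    program before sampling). Negative binomial sampling uses the
    mean/dispersion parameterization with variance ``mu + mu**2/theta``.
    """

    cell_types: list
    n_genes: int
    program_means: np.ndarray
    dispersion: float = 10.0
    library_size_range: tuple = (2000, 8000)
    mito_fraction: float = 0.05
    n_mito_genes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.program_means = np.atleast_2d(np.asarray(self.program_means, float))
        if self.program_means.shape != (len(self.cell_types), self.n_genes):
            raise ValueError("program_means must be (n_types, n_genes)")
        if (self.program_means < 0).any():
            raise ValueError("program_means must be non-negative")
        if np.asarray(self.dispersion).min() <= 0:
            raise ValueError("dispersion must be positive")
        for name, _tag, n_cells in self.cell_types:
            if n_cells < 1:
                raise ValueError(f"cell type {name!r} must have >= 1 cell")

    @property
    def gene_ids(self) -> np.ndarray:
        mito = [f"MT-G{i}" for i in range(self.n_mito_genes)]
        rest = [f"G{i}" for i in range(self.n_genes - self.n_mito_genes)]
        return np.array(mito + rest, dtype=object)

    @property
    def lineage_tags(self) -> dict:
        return {name: tag for name, tag, _n in self.cell_types}


def random_atlas_spec(n_types: int = 4, n_genes: int = 400,
                      cells_per_type: int = 100, markers_per_type: int = 30,
                      background: float = 0.5, marker_level: float = 20.0,
                      dispersion: float = 10.0, mito_fraction: float = 0.05,
                      disjoint: bool = False, seed: int = 0,
                      lineages: list | None = None) -> AtlasSpec:
    """Build an atlas of well-separated expression programs.

    Each type receives an exclusive block of highly expressed marker genes
    on top of a shared low background (``background=0`` or ``disjoint=True``
    gives fully disjoint supports). Mitochondrial genes carry
    ``mito_fraction`` of each program's mass.
    """
    rng = np.random.default_rng(seed)
    n_mito = 10
    if lineages is None:
        lineages = ["lineage%d" % (i % 2) for i in range(n_types)]
    names = [f"type{i}" for i in range(n_types)]
    if disjoint:
        background = 0.0
    means = np.full((n_types, n_genes), background, dtype=float)
    means[:, :n_mito] = 0.0
    start = n_mito
    for t in range(n_types):
        block = slice(start, start + markers_per_type)
        means[t, block] = marker_level * (0.5 + rng.random(markers_per_type))
        start += markers_per_type
    if start > n_genes:
        raise ValueError("n_genes too small for the requested marker blocks")
    # give mito genes mito_fraction of each row's total mass
    for t in range(n_types):
        tot = means[t].sum()
        means[t, :n_mito] = mito_fraction * tot / ((1 - mito_fraction) * n_mito)
    return AtlasSpec(cell_types=[(names[i], lineages[i], cells_per_type)
                                 for i in range(n_types)],
                     n_genes=n_genes, program_means=means,
                     dispersion=dispersion, mito_fraction=mito_fraction,
                     n_mito_genes=n_mito, seed=seed)


def demo_atlas_spec(cells_per_type: int = 120, n_genes: int = 600,
                    dispersion: float = 10.0, seed: int = 0) -> AtlasSpec:
    """A small hematopoietic-like atlas with a B-lineage gradient.

    Types follow the B-lymphopoiesis hierarchy (HSC -> LMPP -> ELP ->
    pre-pro-B -> pro-B -> pre-B -> naive-B) plus myeloid (MOP, monocyte)
    and T cells. Adjacent B stages share part of their program so the
    gradient is graded rather than block-diagonal, mimicking a
    developmental continuum.
    """
    order = [
        ("HSC", "progenitor"), ("LMPP", "progenitor"), ("ELP", "lymphoid"),
        ("pre-pro-B", "lymphoid"), ("pro-B", "lymphoid"), ("pre-B", "lymphoid"),
        ("naive-B", "lymphoid"), ("MOP", "myeloid"), ("monocyte", "myeloid"),
        ("T", "lymphoid"),
    ]
    rng = np.random.default_rng(seed)
    n_types = len(order)
    n_mito = 10
    block = 30
    means = np.full((n_types, n_genes), 0.4, dtype=float)
    means[:, :n_mito] = 0.0
    # B-lineage gradient: the first 7 types overlap half a block with the
    # next stage; myeloid/T get exclusive blocks.
    for t in range(n_types):
        lo = n_mito + t * block - (block // 2 if 0 < t <= 6 else 0)
        hi = n_mito + (t + 1) * block
        means[t, lo:hi] = 25.0 * (0.5 + rng.random(hi - lo))
    mito_fraction = 0.05
    for t in range(n_types):
        tot = means[t].sum()
        means[t, :n_mito] = mito_fraction * tot / ((1 - mito_fraction) * n_mito)
    return AtlasSpec(cell_types=[(n, tag, cells_per_type) for n, tag in order],
                     n_genes=n_genes, program_means=means,
                     dispersion=dispersion, mito_fraction=mito_fraction,
                     n_mito_genes=n_mito, seed=seed)


def gen_reference_cells(spec: AtlasSpec) -> CellMatrix:
    """Sample a labeled sparse single-cell count matrix from ``spec``.

    Per cell: a library size is drawn uniformly from
    ``library_size_range``; per-gene means are the type's program
    frequencies scaled to that library size; counts are gamma-Poisson
    (negative binomial) with dispersion ``theta``.
    """
    rng = np.random.default_rng(spec.seed)
    theta = float(spec.dispersion)
    lo, hi = spec.library_size_range
    cols, labels, cell_ids = [], [], []
    for t, (name, _tag, n_cells) in enumerate(spec.cell_types):
        program = spec.program_means[t]
        tot = program.sum()
        if tot <= 0:
            raise ValueError(f"degenerate type {name!r}: all-zero program")
        freq = program / tot
        lib = rng.uniform(lo, hi, size=n_cells)
        mu = lib[:, None] * freq[None, :]
        lam = rng.gamma(theta, mu / theta)
        counts = rng.poisson(lam)
        cols.append(sp.csr_matrix(counts))
        labels.extend([name] * n_cells)
        cell_ids.extend(f"{name}-{i}" for i in range(n_cells))
    counts = sp.vstack(cols).T.tocsr()  # genes x cells
    gene_ids = spec.gene_ids
    return CellMatrix(counts=counts, gene_ids=gene_ids,
                      cell_ids=np.array(cell_ids, dtype=object),
                      labels=np.array(labels, dtype=object),
                      mito_genes=frozenset(gene_ids[:spec.n_mito_genes]))


# --------------------------------------------------------------------------
# Bulk mixtures
# --------------------------------------------------------------------------

@dataclass
class BulkTruth:
    """Ground-truth mixing weights for one simulated bulk sample."""

    fractions: np.ndarray
    unexplained_fraction: float = 0.0
    depth: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if (self.fractions < 0).any() or self.unexplained_fraction < 0:
            raise ValueError("fractions must be non-negative")
        total = self.fractions.sum() + self.unexplained_fraction
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError("fractions + unexplained_fraction must sum to 1")


def offref_program(n_genes: int, seed: int = 7) -> np.ndarray:
    """An independent held-out expression program over the gene universe.

    Used as the generating profile of the "unexplained" bulk component;
    it is never shown to the deconvolution fitter, which models the
    unexplained signal with a flat intercept instead.
    """
    rng = np.random.default_rng(seed)
    raw = rng.gamma(0.3, 1.0, size=n_genes)
    return raw / raw.sum()


def gen_bulk_mixture(profiles: ReferenceProfiles, truth: BulkTruth,
                     offref: np.ndarray | None = None) -> np.ndarray:
    """Draw one bulk count vector from a known mixture of reference profiles.

    counts ~ Poisson(depth * (sum_k f_k p_gk + f_unexpl * u_g)) where ``u``
    is the held-out off-reference program.
    """
    if truth.depth <= 0:
        raise ValueError("depth must be positive")
    if len(truth.fractions) != profiles.n_types:
        raise ValueError("fractions must match the number of reference types")
    rate = profiles.profile @ truth.fractions
    if truth.unexplained_fraction > 0:
        if offref is None:
            offref = offref_program(len(profiles.gene_ids), seed=truth.seed + 7)
        rate = rate + truth.unexplained_fraction * offref
    rng = np.random.default_rng(truth.seed)
    return rng.poisson(truth.depth * rate)


# --------------------------------------------------------------------------
# Variant tables
# --------------------------------------------------------------------------

BRANCHES = ("embryonic", "leukemia-common", "ALL-private", "AML-private")


@dataclass
class PhyloTruth:
    """Ground truth for a remission/ALL/AML somatic variant table.

    ``branch_counts`` maps branch names to substitution counts; recognized
    branches are embryonic, leukemia-common, ALL-private, AML-private plus
    the optional subclonal components ALL-subclonal / AML-subclonal.
    ``purity`` applies to both tumor samples; variants on tumor branches sit
    at VAF = purity * n_alt_copies / total_copies in carrying samples
    (diploid heterozygous: purity/2) and 0 elsewhere. Embryonic variants
    are additionally mosaic in the remission sample at ``mosaic_vaf``.
    Germline sites sit at VAF 0.5 in every sample (0.95 on X/Y for XY
    cases); artifact sites carry a shared low error rate in all samples.
    """

    branch_counts: dict = field(default_factory=lambda: {
        "embryonic": 2, "leukemia-common": 6,
        "ALL-private": 30, "AML-private": 40})
    purity: float = 0.95
    depth_mean: float = 40.0
    germline_sites: int = 30
    error_sites: int = 20
    error_rate: float = 0.002
    mosaic_vaf: float = 0.125
    subclonal_ccf: float = 0.3
    sex: str = "XX"
    sex_germline_sites: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for b, n in self.branch_counts.items():
            if n < 0:
                raise ValueError(f"branch_counts[{b!r}] must be >= 0")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")
        if self.sex not in ("XX", "XY"):
            raise ValueError("sex must be 'XX' or 'XY'")


SAMPLES = ("remission", "ALL", "AML")


def gen_variant_table(truth: PhyloTruth) -> pd.DataFrame:
    """Simulate a long-format variant read-count table for the trio.

    Returns a DataFrame with one row per (variant, sample):
    chrom, pos, ref, alt, sample, alt_reads, total_reads, plus a
    ``truth_class`` column recording the generating category (branch name,
    "germline" or "artifact").

    Coverage: per-site total reads are Poisson with mean
    ``1.8 * depth_mean`` for remission and ``0.75 * depth_mean`` per
    tumor (the remission sample is sequenced deeper so that embryonic
    mosaic variants at ``mosaic_vaf`` are both detectable and separable
    from germline heterozygosity; the trio mean stays near
    ``depth_mean``).
    """
    rng = np.random.default_rng(truth.seed)
    het = truth.purity / 2.0
    vaf_rows = []  # (truth_class, chrom, vaf_remission, vaf_ALL, vaf_AML)
    bc = dict(truth.branch_counts)
    for _ in range(bc.pop("embryonic", 0)):
        vaf_rows.append(("embryonic", "auto", truth.mosaic_vaf, het, het))
    for _ in range(bc.pop("leukemia-common", 0)):
        vaf_rows.append(("leukemia-common", "auto", 0.0, het, het))
    for _ in range(bc.pop("ALL-private", 0)):
        vaf_rows.append(("ALL-private", "auto", 0.0, het, 0.0))
    for _ in range(bc.pop("AML-private", 0)):
        vaf_rows.append(("AML-private", "auto", 0.0, 0.0, het))
    sub = truth.subclonal_ccf * het
    for _ in range(bc.pop("ALL-subclonal", 0)):
        vaf_rows.append(("ALL-subclonal", "auto", 0.0, sub, 0.0))
    for _ in range(bc.pop("AML-subclonal", 0)):
        vaf_rows.append(("AML-subclonal", "auto", 0.0, 0.0, sub))
    if bc:
        raise ValueError(f"unknown branch names: {sorted(bc)}")
    for _ in range(truth.germline_sites):
        vaf_rows.append(("germline", "auto", 0.5, 0.5, 0.5))
    sex_vaf = 0.95 if truth.sex == "XY" else 0.5
    for _ in range(truth.sex_germline_sites):
        vaf_rows.append(("germline", "X", sex_vaf, sex_vaf, sex_vaf))
    for _ in range(truth.error_sites):
        e = truth.error_rate
        vaf_rows.append(("artifact", "auto", e, e, e))

    depth_means = {"remission": _NORMAL_DEPTH_SHARE * truth.depth_mean,
                   "ALL": _TUMOR_DEPTH_SHARE * truth.depth_mean,
                   "AML": _TUMOR_DEPTH_SHARE * truth.depth_mean}
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    records = []
    autos = itertools.cycle([str(c) for c in range(1, 23)])
    pos_counter = 0
    for cls, chrom_kind, v_rem, v_all, v_aml in vaf_rows:
        pos_counter += 1
        chrom = "X" if chrom_kind == "X" else next(autos)
        pos = 10_000 + 1_000 * pos_counter + int(rng.integers(0, 1000))
        ref, alt = rng.choice(bases, size=2, replace=False)
        for sample, vaf in zip(SAMPLES, (v_rem, v_all, v_aml)):
            dep = int(rng.poisson(depth_means[sample]))
            alt_reads = int(rng.binomial(dep, vaf)) if dep > 0 else 0
            records.append((chrom, pos, ref, alt, sample, alt_reads, dep, cls))
    return pd.DataFrame.from_records(
        records, columns=["chrom", "pos", "ref", "alt", "sample",
                          "alt_reads", "total_reads", "truth_class"])


# --------------------------------------------------------------------------
# Mutational signatures
# --------------------------------------------------------------------------

def _sbs96_channels() -> list:
    subs = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    flanks = ["A", "C", "G", "T"]
    return [f"{l}[{s}]{r}" for s in subs for l in flanks for r in flanks]


SBS96_CHANNELS = _sbs96_channels()


def synthetic_signature_catalog(n_signatures: int = 5, concentration: float = 0.05,
                                seed: int = 0) -> pd.DataFrame:
    """A synthetic 96-channel signature catalog (COSMIC-style layout).

    Sparse Dirichlet draws give well-separated spectra; columns sum to 1.
    Synthetic stand-in for a reference SBS catalog — names are SYN1..SYNk.
    """
    rng = np.random.default_rng(seed)
    mat = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    return pd.DataFrame(mat, index=SBS96_CHANNELS,
                        columns=[f"SYN{i+1}" for i in range(n_signatures)])


def gen_signature_counts(exposures, n: int, catalog: pd.DataFrame,
                         seed: int = 0) -> np.ndarray:
    """Multinomial 96-channel counts from a known signature mixture."""
    if n < 0:
        raise ValueError("mutation count n must be >= 0")
    w = np.asarray(exposures, dtype=float)
    if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("exposures must be non-negative and sum to 1")
    mat = catalog.to_numpy(dtype=float)
    if mat.shape[0] != 96 or mat.shape[1] != len(w):
        raise ValueError("catalog must be 96 x n_signatures")
    p = mat @ w
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, p)
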
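"""End-to-end orchestration of the synthetic demonstration pipeline.

``run(config)`` executes the stages in dependency order on synthetic
data with known ground truth, writes stage artifacts under
``config.out_dir`` and records a manifest (package version, parameters,
seeds, SHA-256 checksums of outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import __version__
from .atlas import build_profiles, normalize_log1p, qc_filter
from .config import RunConfig
from .containers import CellMatrix
from .core import (build_marker_pairs, core_overlap, de_nb_wald,
                   lineage_specificity, mc_enrichment, pair_coexpression,
                   pseudobulk)
from .deconvolution import deconvolve_cohort, elp_ratio, fit_exposures
from .matching import call_cells, predict_similarity, summarize_clusters, train_matcher
from .phylogeny import (VariantTable, assign_branches, depth_filter,
                        fit_clonality_mixture, germline_filter,
                        site_error_model, time_origin)
from .signatures import fit_signature_exposures
from .synthetic import (BulkTruth, PhyloTruth, demo_atlas_spec,
                        gen_bulk_mixture, gen_reference_cells,
                        gen_signature_counts, gen_variant_table,
                        synthetic_signature_catalog)

logger = logging.getLogger(__name__)

__all__ = ["run"]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    os.makedirs(config.out_dir, exist_ok=True)
    t0 = time.time()
    manifest = {"version": __version__, "config": config.to_dict(),
                "stages": [], "outputs": {}}
    ctx = {}

    def record(stage, paths):
        manifest["stages"].append(stage)
        for p in paths:
            manifest["outputs"][os.path.basename(p)] = _sha256(p)

    for stage in config.stages:
        logger.info("stage %s", stage)
        paths = _STAGES[stage](config, ctx)
        record(stage, paths)

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    mpath = os.path.join(config.out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _stage_simulate(cfg: RunConfig, ctx: dict):
    spec = demo_atlas_spec(cells_per_type=cfg.cells_per_type,
                           n_genes=cfg.n_genes, seed=cfg.seed)
    cells = gen_reference_cells(spec)
    ctx["spec"], ctx["cells"] = spec, cells
    prefix = os.path.join(cfg.out_dir, "atlas_")
    cells.write(prefix)
    return [prefix + s for s in ("matrix.mtx", "genes.tsv", "barcodes.tsv",
                                 "labels.tsv")]


def _stage_atlas(cfg: RunConfig, ctx: dict):
    cells = qc_filter(ctx["cells"], min_genes=cfg.min_genes,
                      max_mito=cfg.max_mito)
    profiles = build_profiles(cells, lineage_tags=ctx["spec"].lineage_tags)
    ctx["qc_cells"] = cells
    ctx["normalized"] = normalize_log1p(cells, target_sum=cfg.target_sum)
    ctx["profiles"] = profiles
    p = os.path.join(cfg.out_dir, "profiles.tsv")
    m = os.path.join(cfg.out_dir, "profiles_meta.json")
    profiles.write(p, m)
    return [p, m]


def _stage_deconvolve(cfg: RunConfig, ctx: dict):
    profiles = ctx["profiles"]
    rng = np.random.default_rng(cfg.seed + 1)
    K = profiles.n_types
    bulks, subtypes = {}, {}
    elp_idx = profiles.cell_type_names.index("ELP")
    for i in range(cfg.n_bulk_samples):
        frac = np.zeros(K)
        if i % 2 == 0:  # ELP-dominated leukemia-like mixture
            frac[elp_idx] = 0.8
            frac += 0.2 * rng.dirichlet(np.ones(K))
            subtype = "ELP-like"
        else:           # later-B dominated mixture
            for t in ("pro-B", "pre-B", "naive-B"):
                frac[profiles.cell_type_names.index(t)] = 0.3
            frac += 0.1 * rng.dirichlet(np.ones(K))
            subtype = "later-B"
        frac /= frac.sum()
        truth = BulkTruth(fractions=frac, unexplained_fraction=0.0,
                          depth=cfg.bulk_depth, seed=cfg.seed + 10 + i)
        bulks[f"bulk{i}"] = gen_bulk_mixture(profiles, truth)
        subtypes[f"bulk{i}"] = subtype
    table = pd.DataFrame(bulks, index=profiles.gene_ids)
    shared = min(500, len(profiles.gene_ids))
    exposures, means = deconvolve_cohort(table, profiles, subtypes=subtypes,
                                         min_shared_genes=shared)
    ratios = {}
    for s in exposures.index:
        e = fit_exposures(table[s].to_numpy(), profiles)
        ratios[s] = elp_ratio(e)
    exposures["elp_ratio"] = pd.Series(ratios)
    exposures["subtype"] = pd.Series(subtypes)
    p1 = os.path.join(cfg.out_dir, "exposures.tsv")
    p2 = os.path.join(cfg.out_dir, "subtype_means.tsv")
    exposures.rename_axis("sample").to_csv(p1, sep="\t")
    means.rename_axis("subtype").to_csv(p2, sep="\t")
    return [p1, p2]


def _stage_match(cfg: RunConfig, ctx: dict):
    norm = ctx["normalized"]
    rng = np.random.default_rng(cfg.seed + 2)
    n = norm.n_cells
    holdout = rng.random(n) < 0.25
    model = train_matcher(norm.subset_cells(~holdout), alpha=cfg.alpha,
                          folds=cfg.folds, n_lambdas=cfg.n_lambdas,
                          seed=cfg.seed)
    query = norm.subset_cells(holdout)
    probs = predict_similarity(model, query)
    summary = summarize_clusters(probs, query.labels)
    bands = call_cells(probs, hi=cfg.hi_threshold, lo=cfg.lo_threshold)
    acc = float((probs.idxmax(axis=1).to_numpy() == query.labels).mean())
    ctx["match_accuracy"] = acc
    p1 = os.path.join(cfg.out_dir, "match_model.tsv")
    p2 = os.path.join(cfg.out_dir, "match_model.json")
    p3 = os.path.join(cfg.out_dir, "match_cluster_means.tsv")
    p4 = os.path.join(cfg.out_dir, "match_bands.tsv")
    model.save(p1, p2)
    summary.rename_axis("cluster").to_csv(p3, sep="\t")
    bands.rename_axis("cell_type").to_csv(p4, sep="\t")
    return [p1, p2, p3, p4]


def _stage_phylo(cfg: RunConfig, ctx: dict):
    truth = PhyloTruth(purity=cfg.purity, depth_mean=cfg.depth_mean,
                       seed=cfg.seed + 3)
    long = gen_variant_table(truth)
    vt = VariantTable.from_long(long)
    germline_filter(vt, q_cutoff=cfg.q_cutoff, pool=cfg.pool)
    depth_filter(vt, auto_range=cfg.auto_depth_range,
                 sexchrom_range=cfg.sexchrom_depth_range)
    site_error_model(vt, rho_threshold=cfg.rho_threshold)
    phylo = assign_branches(vt, min_alt=cfg.min_alt)
    divisions = time_origin(phylo.branch_counts["leukemia-common"],
                            rate_min=cfg.mutation_rate_min)
    # clonality on the ALL sample's retained tumor variants
    ja = vt.samples.index("ALL")
    tumor = vt.retained() & vt.branch.isin(
        ["leukemia-common", "ALL-private", "embryonic"]).to_numpy()
    mix = fit_clonality_mixture(vt.alt_reads[tumor, ja],
                                vt.total_reads[tumor, ja],
                                purity=cfg.purity, seed=cfg.seed)
    report = {"branch_counts": phylo.branch_counts,
              "n_inconsistent": phylo.n_inconsistent,
              "newick": phylo.newick(),
              "max_divisions_leukemia_common": divisions,
              "clonality": {"K": mix.K, "p": mix.p.tolist(),
                            "pi": mix.pi.tolist(), "classes": mix.classes,
                            "bic": mix.bic}}
    p1 = os.path.join(cfg.out_dir, "variants_flagged.tsv")
    p2 = os.path.join(cfg.out_dir, "phylogeny.json")
    out = pd.concat([vt.meta, vt.flags,
                     vt.branch.rename("branch")], axis=1)
    out.to_csv(p1, sep="\t", index=False)
    with open(p2, "w") as fh:
        json.dump(report, fh, indent=2)
    ctx["phylo_report"] = report
    return [p1, p2]


def _stage_signatures(cfg: RunConfig, ctx: dict):
    catalog = synthetic_signature_catalog(n_signatures=5, seed=cfg.seed + 4)
    counts = gen_signature_counts([0.7, 0.3, 0, 0, 0], 500, catalog,
                                  seed=cfg.seed + 5)
    exp = fit_signature_exposures(counts, catalog,
                                  retain_frac=cfg.retain_frac)
    p1 = os.path.join(cfg.out_dir, "signature_exposures.tsv")
    pd.DataFrame({"fitted_count": exp.counts,
                  "retained": [s in exp.retained for s in exp.counts.index]}
                 ).rename_axis("signature").to_csv(p1, sep="\t")
    ctx["signature_exposure"] = exp
    return [p1]


def _stage_core(cfg: RunConfig, ctx: dict):
    norm = ctx["normalized"]
    raw = ctx["qc_cells"]
    rng = np.random.default_rng(cfg.seed + 6)
    labels = np.asarray(raw.labels)
    # pseudobulk replicates: ELP cells split into 4 pseudo-replicates vs
    # pre-B cells split into 4, with a planted fold change on marker genes
    reps = {}
    for t in ("ELP", "pre-B"):
        idx = np.flatnonzero(labels == t)
        rng.shuffle(idx)
        for r, part in enumerate(np.array_split(idx, 4)):
            reps.update({f"{t}-rep{r}": part})
    grouping = np.full(raw.n_cells, "other", dtype=object)
    for name, idx in reps.items():
        grouping[idx] = name
    pb = pseudobulk(raw.subset_cells(grouping != "other"),
                    grouping[grouping != "other"])
    res = de_nb_wald(pb, [c for c in pb.columns if c.startswith("ELP")],
                     [c for c in pb.columns if c.startswith("pre-B")],
                     padj_cut=cfg.padj_cut, lfc_cut=cfg.lfc_cut)
    hits = list(res.index[res["significant"].fillna(False)])
    core = core_overlap(hits, hits) if hits else []
    lineages = lineage_specificity(norm, list(norm.gene_ids),
                                   ctx["spec"].lineage_tags,
                                   on_frac=cfg.on_frac, off_frac=cfg.off_frac)
    enr = mc_enrichment(core_size=455, target_set_size=1052,
                        observed_overlap=63, universe_size=cfg.universe_size,
                        reps=cfg.enrichment_reps, seed=cfg.seed + 7)
    myeloid = [g for g, l in lineages.items() if l == "myeloid"][:4]
    lymphoid = [g for g, l in lineages.items() if l == "lymphoid"][:4]
    pairs = build_marker_pairs(myeloid, lymphoid) if myeloid and lymphoid else []
    coex = (pair_coexpression(norm, norm.labels, pairs)
            if pairs else pd.DataFrame())
    p1 = os.path.join(cfg.out_dir, "core_de.tsv")
    p2 = os.path.join(cfg.out_dir, "core_report.json")
    res.rename_axis("gene").to_csv(p1, sep="\t")
    with open(p2, "w") as fh:
        json.dump({"n_de": len(hits), "n_core": len(core),
                   "lineage_tags": {g: l for g, l in lineages.items()
                                    if l not in ("none", "shared")},
                   "enrichment": {"null_mean": enr.null_mean,
                                  "null_sd": enr.null_sd,
                                  "p_empirical": enr.p_empirical,
                                  "p_hypergeom": enr.p_hypergeom},
                   "n_pairs": len(pairs)}, fh, indent=2)
    paths = [p1, p2]
    if len(coex):
        p3 = os.path.join(cfg.out_dir, "pair_coexpression.tsv")
        coex.to_csv(p3, sep="\t", index=False)
        paths.append(p3)
    return paths


_STAGES = {"simulate": _stage_simulate, "atlas": _stage_atlas,
           "deconvolve": _stage_deconvolve, "match": _stage_match,
           "phylo": _stage_phylo, "signatures": _stage_signatures,
           "core": _stage_core}
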
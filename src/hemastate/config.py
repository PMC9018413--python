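"""Structured run configuration for the end-to-end pipeline.

A run config is a flat YAML mapping of stage selections, file paths and
tunables. Every tunable has a default equal to the pipeline's documented
default; unknown keys are rejected before anything executes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # stage selection (dependency order)
    stages: tuple = ("simulate", "atlas", "deconvolve", "match", "phylo",
                     "signatures", "core")
    out_dir: str = "hemastate_run"
    seed: int = 0
    # synthetic atlas size
    cells_per_type: int = 120
    n_genes: int = 600
    # atlas / QC
    min_genes: int = 200
    max_mito: float = 0.20
    target_sum: float = 10_000.0
    # deconvolution
    n_bulk_samples: int = 6
    bulk_depth: int = 1_000_000
    # matching
    alpha: float = 0.99
    folds: int = 10
    n_lambdas: int = 20
    hi_threshold: float = 0.8
    lo_threshold: float = 0.2
    # phylogeny
    q_cutoff: float = 1e-5
    pool: str = "normal"
    auto_depth_range: tuple = (20, 60)
    sexchrom_depth_range: tuple = (10, 30)
    rho_threshold: float = 0.1
    min_alt: int = 3
    purity: float = 0.95
    depth_mean: float = 40.0
    mutation_rate_min: float = 0.9
    # signatures
    retain_frac: float = 0.02
    low_count: int = 100
    # core transcriptome
    padj_cut: float = 0.05
    lfc_cut: float = 1.0
    enrichment_reps: int = 1000
    universe_size: int = 33_660
    on_frac: float = 0.25
    off_frac: float = 0.05

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("stages", "auto_depth_range", "sexchrom_depth_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    return RunConfig.from_mapping(data)
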
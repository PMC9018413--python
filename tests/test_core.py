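"""Pseudobulk DE, overlap, enrichment, lineage tags, pair coexpression."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

import hemastate as hs
from hemastate import CellMatrix
from hemastate.synthetic import gen_reference_cells, random_atlas_spec


def _nb_counts(rng, mu, n, theta=10.0):
    return rng.poisson(rng.gamma(theta, np.outer(mu, np.ones(n)) / theta))


class TestPseudobulk:
    def test_identity_additivity_conservation(self, atlas3):
        _spec, cells = atlas3
        sub = cells.subset_cells(np.arange(6))
        per_cell = hs.pseudobulk(sub, [f"g{i}" for i in range(6)])
        assert np.allclose(per_cell.to_numpy(), sub.counts.toarray())
        merged = hs.pseudobulk(sub, ["a", "a", "a", "b", "b", "b"])
        split = hs.pseudobulk(sub, ["a1", "a2", "a2", "b", "b", "b"])
        assert np.allclose(merged["a"],
                           split["a1"] + split["a2"])
        assert merged.to_numpy().sum() == sub.counts.sum()

    def test_empty_group_rejected(self, atlas3):
        _spec, cells = atlas3
        with pytest.raises(ValueError, match="cover"):
            hs.pseudobulk(cells.subset_cells(np.arange(4)), ["a", "a"])


class TestDifferentialExpression:
    def test_null_calibration(self):
        rng = np.random.default_rng(42)
        G = 2000
        mu = rng.lognormal(4, 1.2, G)
        counts = pd.DataFrame(_nb_counts(rng, mu, 10),
                              index=[f"g{i}" for i in range(G)],
                              columns=[f"s{j}" for j in range(10)])
        res = hs.de_nb_wald(counts, [f"s{j}" for j in range(5)],
                            [f"s{j}" for j in range(5, 10)])
        p = res["pvalue"].dropna()
        assert stats.kstest(p, "uniform").statistic <= 0.05
        assert (p < 0.05).mean() <= 0.07
        assert res["significant"].sum() <= 2

    def test_power_and_fdr_on_planted_changes(self):
        rng = np.random.default_rng(7)
        G = 2000
        mu = rng.lognormal(4, 1.2, G)
        de_idx = rng.choice(G, 100, replace=False)
        mu_b = mu.copy()
        mu_b[de_idx] *= 4.0
        counts = pd.DataFrame(
            np.hstack([_nb_counts(rng, mu, 5), _nb_counts(rng, mu_b, 5)]),
            index=[f"g{i}" for i in range(G)],
            columns=[f"s{j}" for j in range(10)])
        res = hs.de_nb_wald(counts, [f"s{j}" for j in range(5)],
                            [f"s{j}" for j in range(5, 10)])
        flag = res["significant"].fillna(False).to_numpy()
        power = flag[de_idx].mean()
        fdr = (flag.sum() - flag[de_idx].sum()) / max(flag.sum(), 1)
        assert power >= 0.70
        assert fdr <= 0.15
        # planted genes are upregulated in group B by ~2 log2 units
        assert res["log2fc"].iloc[de_idx].median() == pytest.approx(2.0,
                                                                    abs=0.3)

    def test_all_zero_gene_reported_na(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(20, size=(50, 6)),
                              index=[f"g{i}" for i in range(50)],
                              columns=list("abcdef"))
        counts.iloc[7] = 0
        res = hs.de_nb_wald(counts, ["a", "b", "c"], ["d", "e", "f"])
        assert np.isnan(res["pvalue"].iloc[7])
        assert not res["significant"].iloc[7]

    def test_needs_replicates(self):
        counts = pd.DataFrame(np.ones((10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="replicates"):
            hs.de_nb_wald(counts, ["a"], ["b"])


class TestOverlap:
    def test_examples(self):
        assert hs.core_overlap(["g1", "g2", "g3"], ["g2", "g3", "g4"]) == \
            ["g2", "g3"]
        assert hs.core_overlap(["a"], ["b"]) == []
        assert hs.core_overlap(["a", "b"], ["a", "b"]) == ["a", "b"]

    def test_commutative_and_idempotent(self):
        a, b = ["x", "y", "z"], ["y", "q", "x"]
        ab = hs.core_overlap(a, b)
        ba = hs.core_overlap(b, a)
        assert set(ab) == set(ba)
        assert hs.core_overlap(ab, ab) == ab

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hs.core_overlap([], ["a"])


class TestEnrichment:
    def test_null_mean_matches_hypergeometric(self):
        enr = hs.mc_enrichment(455, 1052, observed_overlap=20, seed=0)
        assert enr.null_mean == pytest.approx(455 * 1052 / 33660, abs=0.4)

    def test_target_is_universe(self):
        enr = hs.mc_enrichment(100, 500, observed_overlap=100,
                               universe_size=500, seed=1)
        assert enr.p_empirical == 1.0
        assert enr.null_mean == 100.0

    def test_extreme_observation_saturates_empirical_p(self):
        enr = hs.mc_enrichment(455, 1052, observed_overlap=63, reps=1000,
                               seed=2)
        assert enr.p_empirical == pytest.approx(1 / 1001)
        assert enr.p_hypergeom < 1e-20

    def test_moderate_effect_pvalues_agree(self):
        enr = hs.mc_enrichment(455, 1052, observed_overlap=22, reps=4000,
                               seed=3)
        # empirical tail consistent with the exact hypergeometric tail
        se = np.sqrt(enr.p_hypergeom * (1 - enr.p_hypergeom) / 4000)
        assert abs(enr.p_empirical - enr.p_hypergeom) < 4 * se + 2 / 4000

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            hs.mc_enrichment(10, 50, observed_overlap=11)


@pytest.fixture(scope="module")
def tagged_atlas():
    spec = random_atlas_spec(
        n_types=4, n_genes=300, cells_per_type=50, disjoint=True,
        seed=13, mito_fraction=0.0,
        lineages=["lymphoid", "lymphoid", "myeloid", "other"])
    spec.program_means[:, :spec.n_mito_genes] = 0.0
    cells = gen_reference_cells(spec)
    return spec, hs.normalize_log1p(cells)


class TestLineageSpecificity:
    def test_private_program_genes_fully_tagged(self, tagged_atlas):
        spec, norm = tagged_atlas
        lym = [str(g) for g in spec.gene_ids[10:40]]    # type0 markers
        mye = [str(g) for g in spec.gene_ids[70:100]]   # type2 markers
        tags = hs.lineage_specificity(norm, lym + mye, spec.lineage_tags)
        assert (tags[lym] == "lymphoid").all()
        assert (tags[mye] == "myeloid").all()

    def test_ubiquitous_gene_is_shared(self):
        rng = np.random.default_rng(2)
        counts = sp.csr_matrix(rng.poisson(5, size=(5, 60)) + 1)
        cells = CellMatrix(counts, [f"g{i}" for i in range(5)],
                           [f"c{i}" for i in range(60)],
                           labels=["A"] * 30 + ["B"] * 30)
        tags = hs.lineage_specificity(cells, ["g0"],
                                      {"A": "lymphoid", "B": "myeloid"})
        assert tags["g0"] == "shared"

    def test_absent_gene_none_with_warning(self, tagged_atlas):
        spec, norm = tagged_atlas
        with pytest.warns(UserWarning, match="absent"):
            tags = hs.lineage_specificity(norm, ["NOPE"], spec.lineage_tags)
        assert tags["NOPE"] == "none"


class TestPairCoexpression:
    def test_full_cross_count(self):
        pairs = hs.build_marker_pairs([f"m{i}" for i in range(18)],
                                      [f"l{i}" for i in range(4)])
        assert len(pairs) == 72

    def test_zero_gene_zero_scores(self):
        mat = np.zeros((2, 10))
        mat[1] = 3.0
        cells = CellMatrix(sp.csr_matrix(mat), ["ga", "gb"],
                           [f"c{i}" for i in range(10)])
        out = hs.pair_coexpression(cells, ["k"] * 10, [("ga", "gb")])
        assert out["level"].iloc[0] == 0.0
        assert out["fraction"].iloc[0] == 0.0

    def test_independent_expression_fraction_product(self):
        rng = np.random.default_rng(9)
        n = 20_000
        a = (rng.random(n) < 0.5).astype(float)
        b = (rng.random(n) < 0.4).astype(float)
        cells = CellMatrix(sp.csr_matrix(np.vstack([a, b])), ["ga", "gb"],
                           [f"c{i}" for i in range(n)])
        out = hs.pair_coexpression(cells, ["k"] * n, [("ga", "gb")])
        tol = 3 * np.sqrt(0.2 * 0.8 / n)
        assert out["fraction"].iloc[0] == pytest.approx(0.2, abs=tol + 0.01)

    def test_missing_gene_pair_skipped(self):
        cells = CellMatrix(sp.csr_matrix(np.ones((2, 4))), ["ga", "gb"],
                           list("wxyz"))
        out = hs.pair_coexpression(cells, ["k"] * 4,
                                   [("ga", "gb"), ("ga", "missing")])
        assert len(out) == 1
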
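"""Germline/depth/noise filters, branch assignment, clonality EM, timing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hemastate as hs
from hemastate.phylogeny import VariantTable, _betabinom_loglik, _RHO_GRID
from hemastate.synthetic import PhyloTruth, gen_variant_table


def _table(rows):
    """rows: list of (chrom, alt_per_sample, dep_per_sample)."""
    recs = []
    for i, (chrom, alts, deps) in enumerate(rows):
        for s, a, d in zip(("remission", "ALL", "AML"), alts, deps):
            recs.append((chrom, 1000 + i, "A", "T", s, a, d))
    df = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt", "sample",
                                     "alt_reads", "total_reads"])
    return VariantTable.from_long(df)


class TestGermlineFilter:
    def test_half_vaf_is_germline(self):
        vt = _table([("1", (50, 50, 50), (100, 100, 100))])
        g = hs.germline_filter(vt, pool="all")
        # pooled 150/300: P(X <= 150 | 300, 0.5) ~= 0.52
        assert g.iloc[0]
        assert stats.binom.cdf(150, 300, 0.5) == pytest.approx(0.523, abs=0.01)

    def test_low_vaf_is_somatic_candidate(self):
        vt = _table([("1", (10, 0, 0), (100, 1, 1))])
        g = hs.germline_filter(vt, pool="all")
        assert not g.iloc[0]
        # oracle: direct CDF summation
        p = sum(stats.binom.pmf(k, 102, 0.5) for k in range(11))
        assert p < 1e-15

    def test_male_x_high_vaf_germline(self):
        vt = _table([("X", (95, 95, 95), (100, 100, 100))])
        g = hs.germline_filter(vt, sex="XY", pool="all")
        assert g.iloc[0]

    def test_unknown_chromosome_listed(self):
        df = pd.DataFrame([("weird", 5, "A", "T", "remission", 1, 10)],
                          columns=["chrom", "pos", "ref", "alt", "sample",
                                   "alt_reads", "total_reads"])
        with pytest.raises(ValueError, match="accepted names"):
            VariantTable.from_long(df)

    def test_normal_pool_requires_normal_sample(self):
        vt = _table([("1", (5, 5, 5), (30, 30, 30))])
        vt.samples = ["n", "t1", "t2"]
        with pytest.raises(ValueError, match="normal"):
            hs.germline_filter(vt, pool="normal")

    def test_type_i_control_heterozygous_sites(self):
        # simulated het sites at depth 30 must essentially never survive
        rng = np.random.default_rng(123)
        n = 10_000
        rows = [("1", tuple(rng.binomial(30, 0.5, 3)), (30, 30, 30))
                for _ in range(n)]
        vt = _table(rows)
        g = hs.germline_filter(vt, pool="normal")
        assert (~g).mean() <= 1e-3


class TestDepthFilter:
    def test_ranges(self):
        vt = _table([("1", (0, 0, 0), (15, 15, 15)),    # autosome mean 15
                     ("X", (0, 0, 0), (20, 20, 20)),    # X mean 20: kept
                     ("2", (0, 0, 0), (40, 40, 40))])   # kept
        f = hs.depth_filter(vt)
        assert list(f) == [True, False, False]


class TestSiteErrorModel:
    def test_uniform_low_noise_is_artifact(self):
        rng = np.random.default_rng(5)
        vt = _table([("1", tuple(rng.binomial(100, 0.003, 3)),
                      (100, 100, 100)) for _ in range(5)])
        out = hs.site_error_model(vt)
        hit = out["artifact"] | out["absent"]
        assert hit.all()

    def test_subset_presence_is_true_somatic(self):
        vt = _table([("1", (0, 45, 44), (100, 100, 100))])
        out = hs.site_error_model(vt)
        assert not out["artifact"].iloc[0]
        assert out["rho"].iloc[0] > 0.1

    def test_rho_grid_oracle_agreement(self):
        # the chosen rho maximizes the grid log-likelihood by construction;
        # cross-check against an independent evaluation of the same surface
        vt = _table([("1", (0, 45, 44), (100, 100, 100))])
        out = hs.site_error_model(vt)
        alt = np.array([0, 45, 44]); dep = np.array([100, 100, 100])
        mu = np.clip(alt.sum() / dep.sum(), 1e-6, 1 - 1e-6)
        lls = [_betabinom_loglik(alt, dep, mu, r) for r in _RHO_GRID]
        assert out["rho"].iloc[0] == _RHO_GRID[int(np.argmax(lls))]

    def test_all_zero_flagged_absent(self):
        vt = _table([("1", (0, 0, 0), (50, 50, 50))])
        out = hs.site_error_model(vt)
        assert out["absent"].iloc[0] and not out["artifact"].iloc[0]
        assert np.isnan(out["rho"].iloc[0])


class TestBranchAssignment:
    def test_presence_patterns(self):
        vt = _table([("1", (10, 19, 18), (40, 40, 40)),  # embryonic
                     ("2", (0, 20, 21), (40, 40, 40)),   # leukemia-common
                     ("3", (0, 19, 0), (40, 40, 40)),    # ALL-private
                     ("4", (0, 0, 17), (40, 40, 40)),    # AML-private
                     ("5", (12, 0, 0), (40, 40, 40))])   # inconsistent
        ph = hs.assign_branches(vt)
        assert ph.branch_counts == {"embryonic": 1, "leukemia-common": 1,
                                    "ALL-private": 1, "AML-private": 1}
        assert ph.n_inconsistent == 1
        assert ph.newick().startswith("(remission")

    def test_requires_trio(self):
        df = pd.DataFrame([("1", 5, "A", "T", "remission", 1, 10),
                           ("1", 5, "A", "T", "ALL", 1, 10)],
                          columns=["chrom", "pos", "ref", "alt", "sample",
                                   "alt_reads", "total_reads"])
        vt = VariantTable.from_long(df)
        with pytest.raises(ValueError, match="trio"):
            hs.assign_branches(vt)

    def test_end_to_end_recovery_on_generated_case(self):
        truth = PhyloTruth(seed=11)
        vt = VariantTable.from_long(gen_variant_table(truth))
        hs.germline_filter(vt)
        hs.depth_filter(vt)
        hs.site_error_model(vt)
        ph = hs.assign_branches(vt)
        assert ph.branch_counts == truth.branch_counts
        # germline and artifact sites fully flagged
        tc = vt.meta["truth_class"]
        assert vt.flags.loc[tc == "germline", "germline"].all()
        art = vt.flags.loc[tc == "artifact"]
        assert ((art["artifact"] | art["absent"]).mean() >= 0.95)


class TestClonalityMixture:
    def test_single_component_half(self):
        rng = np.random.default_rng(1)
        alt = rng.binomial(1000, 0.5, 50)
        fit = hs.fit_clonality_mixture(alt, np.full(50, 1000), purity=1.0,
                                       seed=0)
        assert fit.K == 1
        assert fit.p[0] == pytest.approx(0.5, abs=0.01)
        assert fit.classes == ["clonal"]

    def test_two_components_recovered(self):
        rng = np.random.default_rng(0)
        alt = np.concatenate([rng.binomial(60, 0.45, 100),
                              rng.binomial(60, 0.12, 100)])
        dep = np.full(200, 60)
        fit = hs.fit_clonality_mixture(alt, dep, purity=0.9, seed=0)
        assert fit.K == 2
        lo, hi = sorted(fit.p)
        assert lo == pytest.approx(0.12, abs=0.03)
        assert hi == pytest.approx(0.45, abs=0.03)
        assert sorted(fit.classes) == ["clonal", "subclonal"]

    def test_bic_formula(self):
        rng = np.random.default_rng(2)
        alt = rng.binomial(80, 0.4, 60)
        fit = hs.fit_clonality_mixture(alt, np.full(60, 80), purity=0.8,
                                       seed=1)
        expect = -2 * fit.loglik + (2 * fit.K - 1) * np.log(60)
        assert fit.bic == pytest.approx(expect)
        assert fit.bic == min(fit.bic_by_k.values())

    def test_component_near_adjusted_target_is_clonal(self):
        # purity 0.9, diploid het target 0.45
        rng = np.random.default_rng(3)
        alt = rng.binomial(200, 0.45, 50)
        fit = hs.fit_clonality_mixture(alt, np.full(50, 200), purity=0.9,
                                       seed=0)
        assert fit.classes[int(np.argmax(fit.pi))] == "clonal"

    def test_validation(self):
        with pytest.raises(ValueError):
            hs.fit_clonality_mixture([1, 2], [10, 10], purity=0.5, K_max=5)
        with pytest.raises(ValueError):
            hs.fit_clonality_mixture([1] * 10, [10] * 10, purity=0.0)


class TestTiming:
    @pytest.mark.parametrize("n,rate,expect", [(6, 0.9, 6.0 / 0.9),
                                               (0, 0.9, 0.0),
                                               (9, 0.9, 10.0)])
    def test_division_bound(self, n, rate, expect):
        assert hs.time_origin(n, rate) == pytest.approx(expect)

    def test_validation(self):
        with pytest.raises(ValueError):
            hs.time_origin(-1)
        with pytest.raises(ValueError):
            hs.time_origin(3, rate_min=0.0)


def test_expected_clonal_vaf():
    assert hs.expected_clonal_vaf(1.0) == 0.5
    assert hs.expected_clonal_vaf(0.9) == pytest.approx(0.45)
    # single-copy male X: at purity 1 every read carries the variant
    assert hs.expected_clonal_vaf(1.0, n_alt_copies=1, tumor_cn=1) == 1.0
    assert hs.expected_clonal_vaf(0.5, n_alt_copies=1, tumor_cn=1) == \
        pytest.approx(1.0 / 3.0)


def test_variant_table_roundtrip_and_validation():
    truth = PhyloTruth(seed=4, germline_sites=2, error_sites=2)
    long = gen_variant_table(truth)
    vt = VariantTable.from_long(long)
    back = vt.to_long()
    assert len(back) == len(long)
    with pytest.raises(ValueError, match="alt_reads"):
        VariantTable(meta=pd.DataFrame({"chrom": ["1"], "pos": [5],
                                        "ref": ["A"], "alt": ["T"]}),
                     samples=["s"], alt_reads=np.array([[5]]),
                     total_reads=np.array([[3]]))
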
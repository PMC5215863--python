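import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from countseg import synthetic as syn
from countseg.enrichment import (
    cobinding_rate,
    coverage_controlled_recall,
    gwas_enrichment,
    tf_state_enrichment,
)
from countseg.io_binning import BinnedGenome, RegionSet
from countseg.segmentation import path_to_segments


def regions(rows):
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestTfEnrichment:
    def test_hand_computed_value(self):
        # genome 1e6 bp, state s covers 1e4, TF has 100 nt of which 80 in s
        g = BinnedGenome(("c",), (10 ** 6,), 200)
        path = np.zeros(g.n_bins, dtype=int)
        path[: 10 ** 4 // 200] = 1
        ann = path_to_segments(path, g)
        peaks = regions([("c", 0, 80), ("c", 500_000, 500_020)])
        res = tf_state_enrichment(peaks, ann, g)
        e = res.set_index("state")["enrichment"]
        assert e["S2"] == pytest.approx(80.0)

    def test_proportional_coverage_gives_unit_enrichment(self):
        g = BinnedGenome(("c",), (10 * 200,), 200)
        ann = path_to_segments(np.array([0] * 5 + [1] * 5), g)
        # one peak fully inside each state, same length: density equal
        peaks = regions([("c", 100, 200), ("c", 1100, 1200)])
        res = tf_state_enrichment(peaks, ann, g)
        assert np.allclose(res["enrichment"], 1.0)

    def test_normalization_sums_to_one(self, simulated):
        ann = simulated["annotation"]
        peaks = syn.plant_reference_regions(ann, 1, 0.8, 100, seed=2)
        res = tf_state_enrichment(peaks, ann)
        assert res["normalized"].sum() == pytest.approx(1.0)

    def test_whole_genome_state_enrichment_is_one(self):
        g = BinnedGenome(("c",), (20 * 200,), 200)
        ann = path_to_segments(np.zeros(g.n_bins, dtype=int), g)
        peaks = regions([("c", 100, 300), ("c", 2000, 2500)])
        res = tf_state_enrichment(peaks, ann, g)
        assert res["enrichment"].iloc[0] == pytest.approx(1.0)

    def test_empty_peaks_error(self):
        g = BinnedGenome(("c",), (10 * 200,), 200)
        ann = path_to_segments(np.zeros(g.n_bins, dtype=int), g)
        empty = RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]).astype(
            {"chrom": str, "start": int, "end": int}))
        with pytest.raises(ValueError, match="zero nucleotides"):
            tf_state_enrichment(empty, ann, g)


class TestCobinding:
    def _ann(self):
        g = BinnedGenome(("c",), (100 * 200,), 200)
        return path_to_segments(np.ones(g.n_bins, dtype=int)
                                - (np.arange(g.n_bins) >= 50), g)

    def test_identical_sets_give_one(self):
        ann = self._ann()
        a = regions([("c", 100, 200), ("c", 400, 500)])
        assert cobinding_rate(a, a, ann, state=1) == 1.0

    def test_disjoint_sets_give_zero(self):
        ann = self._ann()
        a = regions([("c", 100, 200)])
        b = regions([("c", 300, 400)])
        assert cobinding_rate(a, b, ann, state=1) == 0.0

    def test_jaccard_with_partial_overlap(self):
        # A: 4 sites, B: 6 sites, 2 co-occurring pairs -> 2 / (4+6-2)
        ann = self._ann()
        a = regions([("c", 100, 200), ("c", 1000, 1100),
                     ("c", 3000, 3100), ("c", 5000, 5100)])
        b = regions([("c", 150, 250), ("c", 1050, 1150),
                     ("c", 4000, 4100), ("c", 6000, 6100),
                     ("c", 7000, 7100), ("c", 8000, 8100)])
        assert cobinding_rate(a, b, ann, state=1) == pytest.approx(0.25)

    def test_symmetric(self):
        ann = self._ann()
        a = regions([("c", 100, 200), ("c", 1000, 1100)])
        b = regions([("c", 150, 250), ("c", 5000, 5100), ("c", 6000, 6050)])
        assert cobinding_rate(a, b, ann, 1) == cobinding_rate(b, a, ann, 1)

    def test_sites_outside_state_ignored(self):
        ann = self._ann()  # state 1 = first 50 bins = [0, 10000)
        a = regions([("c", 100, 200), ("c", 15000, 15100)])
        b = regions([("c", 100, 200), ("c", 15000, 15100)])
        assert cobinding_rate(a, b, ann, state=1) == 1.0  # only in-state sites

    def test_empty_in_state_returns_zero(self):
        ann = self._ann()
        a = regions([("c", 15000, 15100)])
        assert cobinding_rate(a, a, ann, state=1) == 0.0


class TestGwasEnrichment:
    def _catalog(self, n_trait, k_trait, n_bg, k_bg):
        """SNPs at deterministic positions: 'in' = position < 10000."""
        rows = []
        for i in range(n_trait):
            pos = 100 + i if i < k_trait else 20000 + i
            rows.append(("c", pos, "focal"))
        for i in range(n_bg):
            pos = 5000 + i if i < k_bg else 40000 + i
            rows.append(("c", pos, f"bg{i % 3}"))
        return pd.DataFrame(rows, columns=["chrom", "pos", "trait"])

    def test_p_equals_hypergeometric_tail(self):
        cat = self._catalog(20, 10, 1000, 100)
        reg = regions([("c", 0, 10000)])
        res = gwas_enrichment(cat, {"x": reg}, min_variants=20)
        p = res.loc[res["trait"] == "focal", "p_value"].iloc[0]
        # one-sided tail P(X >= 10), X ~ Hypergeom(N=1020, K=110, n=20)
        oracle = stats.hypergeom.sf(9, 1020, 110, 20)
        assert p == pytest.approx(oracle, rel=1e-10)

    def test_small_traits_excluded(self):
        cat = self._catalog(19, 5, 300, 30)
        reg = regions([("c", 0, 10000)])
        res = gwas_enrichment(cat, {"x": reg}, min_variants=20)
        assert "focal" not in set(res["trait"])

    def test_by_adjustment_hand_example(self):
        padj = multipletests([0.01, 0.02, 0.04], method="fdr_by")[1]
        assert np.allclose(padj, [0.055, 0.055, 0.0733], atol=5e-5)

    def test_by_at_least_bh_and_monotone(self, rng):
        p = rng.random(50)
        by = multipletests(p, method="fdr_by")[1]
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(by >= bh - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(by[order]) >= -1e-12)

    def test_adjusted_at_least_raw(self):
        cat = self._catalog(25, 12, 500, 50)
        reg = regions([("c", 0, 10000)])
        res = gwas_enrichment(cat, {"x": reg})
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()

    def test_missing_column_error(self):
        with pytest.raises(ValueError, match="trait"):
            gwas_enrichment(pd.DataFrame({"chrom": [], "pos": []}), {})


class TestCoverageControlledRecall:
    def test_target_above_coverage_returns_full_set(self, simulated):
        ann = simulated["annotation"]
        sel = ann.segments[ann.segments["state"] == 2]
        reg = RegionSet(sel[["chrom", "start", "end"]].copy())
        cat = syn.plant_snps(ann, [2], 3.0, n_snps=500, n_background=0, seed=1)
        out = coverage_controlled_recall(reg, cat, ann.genome,
                                         coverage_target=1.0, n_samples=20,
                                         seed=0)
        assert out["recall_ci"][0] == out["recall_ci"][1] == out["median_recall"]

    def test_deterministic_given_seed(self, simulated):
        ann = simulated["annotation"]
        sel = ann.segments[ann.segments["state"] == 2]
        reg = RegionSet(sel[["chrom", "start", "end"]].copy())
        cat = syn.plant_snps(ann, [2], 3.0, n_snps=500, n_background=0, seed=1)
        a = coverage_controlled_recall(reg, cat, ann.genome, 0.02, 50, seed=9)
        b = coverage_controlled_recall(reg, cat, ann.genome, 0.02, 50, seed=9)
        assert a == b

    def test_planted_density_ratio_recovered(self, simulated):
        ann = simulated["annotation"]
        genome = ann.genome
        sel = ann.segments[ann.segments["state"] == 2]
        reg = RegionSet(sel[["chrom", "start", "end"]].copy())
        cat = syn.plant_snps(ann, [2], 3.0, n_snps=5000, n_background=0, seed=1)
        out = coverage_controlled_recall(reg, cat, genome, 0.02, 100, seed=5)
        state_bp = reg.total_length()
        out_bp = genome.genome_length - state_bp
        n_in_state = out["median_frequency"]  # per-bp inside sampled state
        total = len(cat)
        in_total = sum(
            1 for _, r in cat.iterrows()
            if ((sel["start"] <= r["pos"]) & (r["pos"] < sel["end"])
                & (sel["chrom"] == r["chrom"])).any())
        density_out = (total - in_total) / out_bp
        assert n_in_state / density_out == pytest.approx(3.0, rel=0.10)

    def test_recall_nondecreasing_in_target(self, simulated):
        ann = simulated["annotation"]
        sel = ann.segments[ann.segments["state"] == 2]
        reg = RegionSet(sel[["chrom", "start", "end"]].copy())
        cat = syn.plant_snps(ann, [2], 3.0, n_snps=1000, n_background=0, seed=2)
        r1 = coverage_controlled_recall(reg, cat, ann.genome, 0.01, 200, seed=1)
        r2 = coverage_controlled_recall(reg, cat, ann.genome, 0.02, 200, seed=1)
        assert r2["median_recall"] >= r1["median_recall"]
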
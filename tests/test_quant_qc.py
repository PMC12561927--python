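import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from chromdar.errors import ValidationError
from chromdar.intervals import RegionSet, TssTable, merge_regions
from chromdar.quant_qc import (CountExperiment, count_fragments,
                               filter_low_accessibility, frip, log2_cpm,
                               pca_factor_association, sample_correlation,
                               tss_enrichment)
from conftest import random_intervals


def meta_for(ids):
    return pd.DataFrame({"sample_id": ids, "individual": ["A"] * len(ids),
                         "treatment": ["VEH"] * len(ids), "time": ["3"] * len(ids)})


class TestCountFragments:
    regions = RegionSet.from_tuples([("chr1", 0, 100), ("chr1", 200, 300)])

    def run(self, frag_tuples):
        frags = {"s1": RegionSet.from_tuples(frag_tuples)}
        return count_fragments(frags, self.regions, meta_for(["s1"]))

    def test_single_overlap(self):
        exp = self.run([("chr1", 50, 150)])
        assert exp.counts[:, 0].tolist() == [1, 0]

    def test_spanning_fragment_touches_both(self):
        exp = self.run([("chr1", 90, 210)])
        assert exp.counts[:, 0].tolist() == [1, 1]
        # but counted once in the FRiP numerator
        assert exp.samples.loc[0, "n_fragments_in_regions"] == 1

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(100):
            regions = merge_regions(RegionSet.from_tuples(random_intervals(rng, 8)))
            frag_tuples = random_intervals(rng, 15)
            exp = count_fragments({"s": RegionSet.from_tuples(frag_tuples)},
                                  regions, meta_for(["s"]))
            expected = oracle.brute_count_overlaps(
                frag_tuples, [(r.chrom, r.start, r.end) for r in regions])
            assert exp.counts[:, 0].tolist() == expected


class TestFrip:
    def test_ratio_and_bounds(self):
        regions = RegionSet.from_tuples([("chr1", 0, 100)])
        inside = [("chr1", 10, 20), ("chr1", 50, 90)]
        outside = [("chr1", 500 + i * 100, 560 + i * 100) for i in range(8)]
        exp = count_fragments({"s": RegionSet.from_tuples(inside + outside)},
                              regions, meta_for(["s"]))
        out = frip(exp)
        assert out.loc[0, "frip"] == pytest.approx(0.2)
        # exactly at the floor passes; strictly below is flagged
        assert not bool(out.loc[0, "below_floor"])
        assert bool(frip(exp, floor=0.25).loc[0, "below_floor"])
        exp_all = count_fragments({"s": RegionSet.from_tuples(inside)},
                                  regions, meta_for(["s"]))
        assert frip(exp_all).loc[0, "frip"] == 1.0

    def test_matrix_only_experiment_rejected(self):
        exp = CountExperiment(RegionSet.from_tuples([("chr1", 0, 10)]),
                              np.array([[5]]), meta_for(["s"]))
        with pytest.raises(ValidationError):
            frip(exp)


class TestLog2Cpm:
    def test_hand_evaluated_value(self):
        exp = CountExperiment(RegionSet.from_tuples([("chr1", 0, 10), ("chr1", 20, 30)]),
                              np.array([[0], [10**6 - 0]]), meta_for(["s"]))
        val = log2_cpm(exp, prior=0.5)[0, 0]
        assert val == pytest.approx(np.log2(0.5 / (1e6 + 1) * 1e6), abs=1e-9)
        assert val == pytest.approx(-1.0, abs=1e-5)

    def test_monotone_in_count(self, rng):
        counts = rng.integers(0, 100, size=(50, 3))
        exp = CountExperiment(
            RegionSet.from_tuples([("chr1", i * 10, i * 10 + 5) for i in range(50)]),
            counts, meta_for(["a", "b", "c"]))
        lcpm = log2_cpm(exp)
        exp2 = CountExperiment(exp.regions, counts + 1, exp.samples)
        lcpm2 = log2_cpm(exp2, lib_sizes=exp.lib_sizes)
        assert (lcpm2 > lcpm).all()

    def test_prior_zero_columns_sum_to_million(self, rng):
        counts = rng.integers(1, 100, size=(30, 2))
        exp = CountExperiment(
            RegionSet.from_tuples([("chr1", i * 10, i * 10 + 5) for i in range(30)]),
            counts, meta_for(["a", "b"]))
        cpm = 2.0 ** log2_cpm(exp, prior=0.0)
        assert np.allclose(cpm.sum(axis=0), 1e6)


class TestFilterLowAccessibility:
    def build(self, counts, chroms):
        regions = RegionSet.from_tuples(
            [(c, i * 1000, i * 1000 + 100) for i, c in enumerate(chroms)])
        return CountExperiment(regions, np.asarray(counts), meta_for(["a", "b"]))

    def test_strict_threshold_and_chromosome_rule(self):
        # engineer a region whose log2-cpm is exactly 0 in both samples:
        # (c + 0.5)/(L + 1) * 1e6 = 1 with c = 1 requires L = 1.5e6 - 1
        c0 = 1
        lib = int(1.5e6) - 1
        filler = lib - c0 - 50
        exp = self.build(
            [[0, 0],                 # below 0 -> removed
             [c0, c0],               # exactly 0 -> kept (strict <)
             [filler, filler],       # high -> kept
             [50, 50]],              # high enough but on chrY -> removed
            ["chr1", "chr1", "chr1", "chrY"])
        lcpm = log2_cpm(exp)
        assert lcpm[1].mean() == pytest.approx(0.0, abs=1e-12)
        filtered, report = filter_low_accessibility(exp)
        kept = set(filtered.regions.region_ids)
        ids = exp.regions.region_ids.tolist()
        assert ids[0] not in kept and ids[3] not in kept
        assert ids[1] in kept and ids[2] in kept
        assert report["n_low_accessibility"] == 1
        assert report["n_dropped_chrom"] == 1

    def test_partition_counts(self, rng):
        counts = rng.integers(0, 2000, size=(40, 2))
        exp = self.build(counts, ["chr1"] * 40)
        filtered, report = filter_low_accessibility(exp)
        assert report["n_kept"] == filtered.n_regions
        assert report["n_kept"] + report["n_low_accessibility"] == report["n_input"]


class TestTssEnrichment:
    def tss(self, positions, strand="+"):
        return TssTable(pd.DataFrame(
            [(f"g{i}", "chr1", p, strand) for i, p in enumerate(positions)],
            columns=["gene_id", "chrom", "tss", "strand"]))

    def test_uniform_depth_gives_one(self):
        # one fragment covering the whole +/-1kb window -> depth 1 everywhere
        frags = RegionSet.from_tuples([("chr1", 0, 20000)])
        assert tss_enrichment(frags, self.tss([5000])) == pytest.approx(1.0)

    def test_central_spike_gives_ten(self):
        base = [("chr1", 0, 20000)]
        # 9 extra fragments exactly over the window containing the TSS
        spike = [("chr1", 5000, 5100)] * 9
        val = tss_enrichment(RegionSet.from_tuples(base + spike), self.tss([5000]))
        assert val == pytest.approx(10.0, rel=0.02)

    def test_scale_invariance(self):
        frags = [("chr1", 0, 20000)] + [("chr1", 5000, 5100)] * 4
        one = tss_enrichment(RegionSet.from_tuples(frags), self.tss([5000]))
        five = tss_enrichment(RegionSet.from_tuples(frags * 5), self.tss([5000]))
        assert one == pytest.approx(five)

    def test_minus_strand_flips_profile(self):
        # asymmetric coverage downstream of a plus-strand TSS
        frags = RegionSet.from_tuples([("chr1", 0, 20000), ("chr1", 5400, 5500)])
        plus = tss_enrichment(frags, self.tss([5000], "+"))
        minus = tss_enrichment(frags, self.tss([5000], "-"))
        assert plus == pytest.approx(minus)  # maximum is flip-invariant

    def test_zero_flank_depth_errors(self):
        frags = RegionSet.from_tuples([("chr1", 5000, 5010)])
        with pytest.raises(ValidationError):
            tss_enrichment(frags, self.tss([5000]))


class TestPcaAndCorrelation:
    def test_separated_groups_load_on_pc1(self, rng):
        n = 12
        meta = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "individual": ["A"] * n,
            "treatment": ["DRUG"] * 6 + ["VEH"] * 6,
            "time": ["3"] * n,
        })
        x = rng.normal(0, 0.1, size=(100, n))
        x[:, :6] += 5.0
        res = pca_factor_association(x, meta, n_pcs=3, factors=("treatment",))
        pc1 = res[(res.pc == 1) & (res.factor == "treatment")].iloc[0]
        assert pc1.p < 1e-10 and pc1.r2 > 0.99

    def test_variance_explained_sums_to_one(self, rng):
        meta = pd.DataFrame({"sample_id": list("abcd"), "individual": list("ABAB"),
                             "treatment": ["D", "D", "V", "V"], "time": ["3"] * 4})
        x = rng.normal(size=(30, 4))
        res = pca_factor_association(x, meta, n_pcs=4)
        ve = res.drop_duplicates("pc")["variance_explained"]
        # 3 non-null components after centering 4 samples
        assert ve.sum() == pytest.approx(1.0, abs=1e-8)

    def test_constant_matrix_errors(self):
        meta = pd.DataFrame({"sample_id": ["a", "b"], "individual": ["A", "B"],
                             "treatment": ["D", "V"], "time": ["3", "3"]})
        with pytest.raises(ValidationError):
            pca_factor_association(np.ones((10, 2)), meta)

    def test_correlation_identity_and_antisymmetry(self, rng):
        x = rng.normal(size=(50, 1))
        mat = np.hstack([x, -x])
        corr = sample_correlation(mat, ["a", "b"])
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_hand_example(self):
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([2.0, 1.0, 5.0])
        corr = sample_correlation(np.column_stack([a, b]), ["a", "b"])
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert corr.loc["a", "b"] == pytest.approx(num / den)
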
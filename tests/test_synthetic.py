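import numpy as np
import pandas as pd
import pytest

from epimemory import methylome as meth
from epimemory import synthetic as syn
from epimemory.types import GenomeSpec, RegionSet


BASELINES = {"fibroblast": 0.75, "hES": 0.82, "primed-hiPS": 0.80}


class TestGenerateMethylome:
    def test_seeded_determinism(self, small_genome):
        a, _ = syn.generate_methylome(small_genome, BASELINES, coverage=10, seed=42)
        b, _ = syn.generate_methylome(small_genome, BASELINES, coverage=10, seed=42)
        for g in BASELINES:
            pd.testing.assert_frame_equal(a[g].df, b[g].df)

    def test_different_seed_differs(self, small_genome):
        a, _ = syn.generate_methylome(small_genome, BASELINES, coverage=10, seed=1)
        b, _ = syn.generate_methylome(small_genome, BASELINES, coverage=10, seed=2)
        assert not a["hES"].df.equals(b["hES"].df)

    def test_zero_nonconversion_spike_in_fully_unmethylated(self, small_genome):
        tabs, _ = syn.generate_methylome(
            small_genome, BASELINES, coverage=20, nonconversion=0.0, seed=3
        )
        for t in tabs.values():
            spike = t.df[t.df["chrom"] == "spike"]
            assert (spike["mc"] == 0).all()

    def test_spike_in_estimates_nonconversion(self, small_genome):
        tabs, _ = syn.generate_methylome(
            small_genome, BASELINES, coverage=30, nonconversion=0.01, seed=4
        )
        est = meth.nonconversion_rate(tabs["hES"], "spike", "CH")
        assert est == pytest.approx(0.01, abs=0.003)

    def test_overlapping_planted_regions_rejected(self, small_genome):
        planted = [
            syn.PlantedRegion("chr1", 1000, 2000, "dmr", {"hES": 0.8}),
            syn.PlantedRegion("chr1", 1500, 2500, "pmd", {"hES": 0.6}),
        ]
        with pytest.raises(ValueError, match="dmr_chr1_1000_2000.*pmd_chr1_1500_2500"):
            syn.generate_methylome(small_genome, BASELINES, planted=planted, seed=0)

    def test_planted_region_outside_contig_rejected(self, small_genome):
        planted = [syn.PlantedRegion("chr2", 290_000, 310_000, "dmr", {"hES": 0.8})]
        with pytest.raises(ValueError, match="outside"):
            syn.generate_methylome(small_genome, BASELINES, planted=planted, seed=0)

    def test_planted_dmr_levels_recovered(self, small_genome):
        planted = [
            syn.PlantedRegion(
                "chr1", 10_000, 11_000, "dmr",
                {"fibroblast": 0.1, "hES": 0.8, "primed-hiPS": 0.12}, label="memory",
            )
        ]
        tabs, truth = syn.generate_methylome(
            small_genome, BASELINES, planted=planted, coverage=30, seed=5
        )
        rs = RegionSet.from_records([("chr1", 10_000, 11_000)], ids=["d"])
        for grp, want in [("fibroblast", 0.1), ("hES", 0.8), ("primed-hiPS", 0.12)]:
            level = meth.weighted_methylation(
                meth.collapse_cg_strands(tabs[grp]), rs, "CG"
            )["d"]
            assert level == pytest.approx(want, abs=0.05)
        assert truth.dmr_truth.loc["dmr_chr1_10000_11000", "label"] == "memory"

    def test_planted_chdmr_lowers_mca(self, small_genome):
        planted = [
            syn.PlantedRegion("chr1", 50_000, 100_000, "chdmr", {"hES": 0.01})
        ]
        tabs, _ = syn.generate_methylome(
            small_genome, BASELINES, planted=planted, coverage=30,
            mca_baselines={"hES": 0.05}, seed=6,
        )
        rs = RegionSet.from_records(
            [("chr1", 50_000, 100_000), ("chr1", 150_000, 200_000)], ids=["in", "out"]
        )
        levels = meth.weighted_methylation(tabs["hES"], rs, "CA", subtract_nonconversion=False)
        assert levels["in"] < levels["out"]

    def test_icr_defaults_to_balanced_level(self, small_genome):
        planted = [syn.PlantedRegion("chr2", 100_000, 102_000, "icr")]
        tabs, _ = syn.generate_methylome(
            small_genome, BASELINES, planted=planted, coverage=50, seed=7
        )
        rs = RegionSet.from_records([("chr2", 100_000, 102_000)], ids=["icr"])
        level = meth.weighted_methylation(
            meth.collapse_cg_strands(tabs["hES"]), rs, "CG"
        )["icr"]
        assert level == pytest.approx(0.5, abs=0.05)


class TestGenerateReadLevelCalls:
    def test_all_methylated_archetype(self):
        recs = syn.generate_read_level_calls("icr", (1, 0, 0), 10, 4, seed=0)
        assert all(rec.calls == (1, 1, 1, 1) for rec in recs)

    def test_all_partial_reads_are_mixed(self):
        recs = syn.generate_read_level_calls("icr", (0, 0, 1), 50, 5, seed=1)
        for rec in recs:
            assert 0 < sum(rec.calls) < len(rec.calls)

    def test_balanced_fractions_recovered(self):
        recs = syn.generate_read_level_calls("icr", (0.5, 0.5, 0), 10_000, 4, seed=2)
        counts = meth.classify_reads(recs).loc["icr"]
        assert counts["methylated"] / 10_000 == pytest.approx(0.5, abs=0.02)
        assert counts["partial"] == 0

    def test_partial_impossible_with_one_cpg(self):
        with pytest.raises(ValueError, match="partial"):
            syn.generate_read_level_calls("icr", (0.5, 0, 0.5), 10, cpgs_per_read=1)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            syn.generate_read_level_calls("icr", (0.5, 0.1, 0.1), 10)


class TestGenerateFeatureTracks:
    def test_fold_zero_never_overlaps_query(self, small_genome):
        query = RegionSet.from_records([("chr1", i * 10_000, i * 10_000 + 2000) for i in range(10)])
        feats = syn.generate_feature_tracks(
            small_genome, query, fold_enrichment=0, n_features=200, seed=0
        )
        from epimemory.enrichment import overlap_count

        assert overlap_count(feats, query) == 0

    def test_widths_and_count(self, small_genome):
        query = RegionSet.from_records([("chr1", 0, 10_000)])
        feats = syn.generate_feature_tracks(
            small_genome, query, feature_width_bp=750, n_features=57, seed=1
        )
        assert len(feats) == 57
        assert (feats.widths() == 750).all()
        assert not (feats.df["chrom"] == "spike").any()

    def test_excessive_fold_rejected(self, small_genome):
        query = RegionSet.from_records([("chr1", 0, 400_000)])
        with pytest.raises(ValueError, match="fold_enrichment"):
            syn.generate_feature_tracks(small_genome, query, fold_enrichment=10, n_features=10)


class TestGenerateInsertionLibrary:
    def test_high_coverage_observes_every_site(self, small_genome):
        lib, truth = syn.generate_insertion_library(10, 100.0, small_genome, seed=0)
        from epimemory.insertions import call_insert_sites, filter_alignments

        kept, _ = filter_alignments(lib)
        clusters = call_insert_sites(kept)
        assert len(clusters) == 10
        assert len(truth.insertion_truth) == 10

    def test_clean_library_passes_all_filters(self, small_genome):
        lib, _ = syn.generate_insertion_library(50, 3.0, small_genome, seed=1)
        from epimemory.insertions import filter_alignments

        kept, tally = filter_alignments(lib)
        assert tally["kept"] == len(lib)
        assert sum(v for k, v in tally.items() if k != "kept") == 0

    def test_noise_reads_violate_exactly_their_criterion(self, small_genome):
        spec = {"non_primary": 0.1, "short": 0.1, "low_mapq": 0.1, "gap": 0.1, "single_mapped": 0.1}
        lib, truth = syn.generate_insertion_library(
            100, 5.0, small_genome, noise_spec=spec, seed=2
        )
        from epimemory.insertions import filter_alignments

        kept, tally = filter_alignments(lib)
        n_good = int(truth.insertion_truth["n_reads"].sum())
        for crit in spec:
            assert tally[crit] == round(0.1 * n_good)
        assert tally["kept"] == n_good

    def test_unique_sites_match_poisson_expectation(self):
        genome = GenomeSpec(contigs=(("chr1", 2_000_000), ("spike", 10_000)))
        lib, truth = syn.generate_insertion_library(1000, 3.0, genome, seed=3)
        from epimemory.insertions import call_insert_sites, filter_alignments

        clusters = call_insert_sites(filter_alignments(lib)[0])
        # exact: one cluster per planted site that drew >= 1 read
        assert len(clusters) == (truth.insertion_truth["n_reads"] > 0).sum()
        # statistical: observed ~ Binomial(1000, 1 - e^-3); 3-sigma window
        expected = 1000 * (1 - np.exp(-3))
        sigma = np.sqrt(1000 * np.exp(-3) * (1 - np.exp(-3)))
        assert abs(len(clusters) - expected) <= 3 * sigma


class TestGenerateTrajectories:
    CENTROIDS = np.array([[0.9, 0.6, 0.2, 0.1], [0.1, 0.4, 0.8, 0.9]])

    def test_zero_noise_members_equal_centroid(self):
        mat, truth = syn.generate_trajectories(
            20, ["d0", "d13", "d21", "p3"], self.CENTROIDS, noise_sd=0, seed=0
        )
        labels = truth.trajectory_truth
        for eid, lab in labels.items():
            assert np.allclose(mat.loc[eid], self.CENTROIDS[lab])

    def test_background_is_flat(self):
        mat, truth = syn.generate_trajectories(
            50, ["a", "b", "c", "d"], self.CENTROIDS, 0.02, background_fraction=0.4, seed=1
        )
        bg = mat.loc[truth.trajectory_truth == -1]
        assert len(bg) == 20
        assert ((bg.max(axis=1) - bg.min(axis=1)) < 0.2).all()

    def test_background_removed_by_dynamic_filter(self):
        from epimemory.trajectories import filter_dynamic_elements

        mat, truth = syn.generate_trajectories(
            60, ["a", "b", "c", "d"], self.CENTROIDS, 0.02, background_fraction=0.5, seed=2
        )
        kept = filter_dynamic_elements(mat, min_change=0.2)
        assert set(kept.index) == set(truth.trajectory_truth.index[truth.trajectory_truth >= 0])
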
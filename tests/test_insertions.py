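import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from epimemory import insertions as ins
from epimemory import synthetic as syn
from epimemory.synthetic import ALIGNMENT_PAIR_COLUMNS
from epimemory.types import GenomeSpec


def make_pair(
    read_id="r",
    chrom="chr1",
    g_start=10_000,
    g_end=12_000,
    strand="+",
    mapq=60,
    is_primary=True,
    g_read=(0, 2000),
    v_read=(2010, 3010),
    v=(0, 1000),
    read_length=3010,
    no_vector=False,
):
    row = {
        "read_id": read_id,
        "chrom": chrom,
        "g_start": g_start,
        "g_end": g_end,
        "strand": strand,
        "mapq": mapq,
        "is_primary": is_primary,
        "g_read_start": g_read[0],
        "g_read_end": g_read[1],
        "v_start": np.nan if no_vector else v[0],
        "v_end": np.nan if no_vector else v[1],
        "v_read_start": np.nan if no_vector else v_read[0],
        "v_read_end": np.nan if no_vector else v_read[1],
        "read_length": read_length,
    }
    return row


def pairs_frame(rows):
    return pd.DataFrame(rows, columns=ALIGNMENT_PAIR_COLUMNS)


class TestFilterAlignments:
    @pytest.mark.parametrize(
        "kwargs,kept",
        [
            ({"g_start": 10_000, "g_end": 10_799}, False),  # length 799
            ({"g_start": 10_000, "g_end": 10_800}, True),  # length 800
            ({"v_read": (2050, 3050)}, True),  # gap 50
            ({"v_read": (2051, 3051)}, False),  # gap 51
            ({"mapq": 59}, False),
            ({"mapq": 60}, True),
            ({"is_primary": False}, False),
            ({"no_vector": True}, False),
        ],
    )
    def test_boundary_cases(self, kwargs, kept):
        frame = pairs_frame([make_pair(**kwargs)])
        out, tally = ins.filter_alignments(frame)
        assert (len(out) == 1) is kept
        assert tally["kept"] == int(kept)

    def test_overlapping_read_intervals_have_zero_gap(self):
        frame = pairs_frame([make_pair(v_read=(1950, 2950))])  # overlaps genome interval
        out, _ = ins.filter_alignments(frame)
        assert len(out) == 1

    def test_mapq_ge_mode(self):
        frame = pairs_frame([make_pair(mapq=70)])
        assert len(ins.filter_alignments(frame)[0]) == 0
        assert len(ins.filter_alignments(frame, mapq_mode="ge")[0]) == 1

    def test_tally_partitions_input(self):
        rows = [
            make_pair(read_id="ok"),
            make_pair(read_id="short", g_end=10_500),
            make_pair(read_id="np", is_primary=False),
            make_pair(read_id="sm", no_vector=True),
        ]
        out, tally = ins.filter_alignments(pairs_frame(rows))
        assert sum(tally.values()) == 4
        assert tally["kept"] == 1 and tally["short"] == 1
        assert tally["non_primary"] == 1 and tally["single_mapped"] == 1

    def test_idempotent_and_order_independent(self, rng):
        lib, _ = syn.generate_insertion_library(
            50, 4.0, GenomeSpec(contigs=(("chr1", 500_000), ("spike", 10_000))),
            noise_spec={"short": 0.1, "gap": 0.1}, seed=0,
        )
        once, _ = ins.filter_alignments(lib)
        twice, _ = ins.filter_alignments(once)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = lib.sample(frac=1, random_state=1)
        out_shuf, _ = ins.filter_alignments(shuffled)
        assert sorted(out_shuf["read_id"]) == sorted(once["read_id"])


class TestReadJunctions:
    @pytest.mark.parametrize(
        "strand,v_read,expected",
        [
            ("+", (2010, 3010), 12_000),  # vector 3' of genome on read, + strand
            ("-", (2010, 3010), 10_000),
            ("+", (0, 1000), 10_000),  # vector 5' of genome
            ("-", (0, 1000), 12_000),
        ],
    )
    def test_junction_side(self, strand, v_read, expected):
        g_read = (0, 2000) if v_read[0] >= 1000 else (1010, 3010)
        frame = pairs_frame([make_pair(strand=strand, v_read=v_read, g_read=g_read)])
        assert ins.read_junctions(frame)["junction"].iloc[0] == expected


def brute_force_single_linkage(positions, interval):
    """O(n^2) oracle: union-find by repeated pairwise merging."""
    positions = sorted(positions)
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(positions)):
        for j in range(len(positions)):
            if abs(positions[i] - positions[j]) <= interval:
                parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(positions):
        groups.setdefault(find(i), []).append(p)
    return sorted(
        (min(g), max(g), len(g)) for g in groups.values()
    )


class TestCallInsertSites:
    def _frame_at(self, positions):
        return pairs_frame(
            [
                make_pair(read_id=f"r{i}", g_start=p - 2000, g_end=p)
                for i, p in enumerate(positions)
            ]
        )

    def test_two_clusters_example(self):
        clusters = ins.call_insert_sites(self._frame_at([10_100, 10_140, 10_400]))
        assert [(c.start, c.end, c.coverage) for c in clusters] == [
            (10_100, 10_141, 2),
            (10_400, 10_401, 1),
        ]

    def test_transitive_chaining(self):
        clusters = ins.call_insert_sites(self._frame_at([10_100, 10_150, 10_200]))
        assert len(clusters) == 1
        assert clusters[0].coverage == 3
        assert (clusters[0].start, clusters[0].end) == (10_100, 10_201)

    def test_empty_input(self):
        assert ins.call_insert_sites(pairs_frame([])) == []

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 60))
            positions = (rng.integers(3000, 50_000, size=n)).tolist()
            clusters = ins.call_insert_sites(self._frame_at(positions))
            got = sorted((c.start, c.end - 1, c.coverage) for c in clusters)
            assert got == brute_force_single_linkage(positions, 50)


class TestZtpEstimator:
    def test_fixed_point_equals_bisection_root(self):
        n, R = 950, 3000
        root = brentq(lambda N: N * (1 - np.exp(-R / N)) - n, n, 20 * n, xtol=1e-9)
        est, converged = ins.ztp_total_sites(n, R)
        assert converged
        assert est == pytest.approx(root, abs=1)
        assert est == pytest.approx(1000, abs=5)

    def test_saturated_limit(self):
        est, converged = ins.ztp_total_sites(10, 1000)
        assert converged
        assert est == pytest.approx(10, abs=1e-6)

    def test_all_singletons_unbounded(self):
        est, converged = ins.ztp_total_sites(100, 100)
        assert not converged and np.isinf(est)

    def test_estimate_at_least_observed(self, rng):
        for lam in (1.0, 3.0, 10.0):
            counts = rng.poisson(lam, 500)
            counts = counts[counts > 0]
            est, converged = ins.ztp_total_sites(len(counts), int(counts.sum()))
            assert est >= len(counts)


class TestEstimateDiversity:
    def _clusters(self, coverages):
        return [
            ins.InsertSiteCluster("chr1", 1000 * i, 1000 * i + 1, int(c), tuple([1000 * i] * int(c)))
            for i, c in enumerate(coverages)
        ]

    def test_point_estimate_and_ci_order(self, rng):
        cov = rng.poisson(3, 1000)
        cov = cov[cov > 0]
        est = ins.estimate_diversity(self._clusters(cov), n_boot=200, seed=0)
        assert est.converged
        assert est.n_observed <= est.n_total_hat
        assert est.ci[0] <= est.n_total_hat <= est.ci[1]

    def test_relative_error_decreases_with_coverage(self, rng):
        errs = []
        for lam in (1.0, 3.0, 10.0):
            rel = []
            for seed in range(5):
                r = np.random.default_rng(seed)
                cov = r.poisson(lam, 1000)
                cov = cov[cov > 0]
                est = ins.estimate_diversity(self._clusters(cov), n_boot=0, seed=0)
                rel.append(abs(est.n_total_hat - 1000) / 1000)
            errs.append(np.mean(rel))
        assert errs[2] < errs[0]

    def test_all_singletons_flagged_unconverged(self):
        est = ins.estimate_diversity(self._clusters([1] * 50), n_boot=50, seed=0)
        assert not est.converged and np.isinf(est.n_total_hat)

    def test_too_few_clusters_is_error(self):
        with pytest.raises(ValueError):
            ins.estimate_diversity(self._clusters([3]))

    def test_cluster_invariants(self):
        with pytest.raises(ValueError):
            ins.InsertSiteCluster("chr1", 0, 10, coverage=2, member_sites=(1,))
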
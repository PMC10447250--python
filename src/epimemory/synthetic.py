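"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the data types produced by a reprogramming
methylome study — whole-genome bisulfite call tables with planted
differentially methylated regions (DMRs), partially methylated domains
(PMDs), megabase-scale low-mCA domains (CH-DMRs) and balanced imprint
control regions (ICRs); per-read CG call patterns; genomic feature tracks
with controlled overlap enrichment; Cas9-enrichment nanopore insertion-read
libraries; and element x time-point methylation trajectory matrices — so
that every downstream statistic can be checked against planted truth
without any external sequencing data.

Simplifications relative to real data are deliberate and documented in the
methods note: CpG sites sit on a fixed 100-bp grid per contig, coverage is
Poisson around the mean depth (floored at 1 inside planted regions so no
planted region is silently unobserved), and methylated-call counts are
binomial at the local true level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import GenomeSpec, MethylomeTable, ReadCallRecord, RegionSet

__all__ = [
    "PlantedRegion",
    "PlantedTruth",
    "generate_methylome",
    "generate_read_level_calls",
    "generate_feature_tracks",
    "generate_insertion_library",
    "generate_trajectories",
]

# offsets of synthetic cytosine sites within each 100-bp tile (1-based):
# plus-strand CpG C at +1, its minus-strand partner at +2, two plus-strand
# CA sites and one CT site to exercise the CH contexts.
_CG_OFFSET = 1
_CA_OFFSETS = (31, 61)
_CT_OFFSET = 81
_TILE = 100


@dataclass(frozen=True)
class PlantedRegion:
    """One planted region with its per-group true methylation level.

    ``kind`` is one of ``dmr``, ``pmd``, ``chdmr``, ``icr``; ``levels`` maps
    group name to the true level inside the region (mCG for dmr/pmd/icr, mCA
    for chdmr); groups absent from the map keep their baseline.  ``label`` is
    the truth class for DMRs (vocabulary of :mod:`epimemory.dmr`).
    """

    chrom: str
    start: int
    end: int
    kind: str
    levels: Mapping[str, float] = field(default_factory=dict)
    label: str | None = None

    @property
    def id(self) -> str:
        return f"{self.kind}_{self.chrom}_{self.start}_{self.end}"

    def to_interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class PlantedTruth:
    """Ground truth attached to a synthetic dataset."""

    dmr_truth: pd.DataFrame | None = None
    domain_truth: dict[str, RegionSet] = field(default_factory=dict)
    icr_truth: pd.DataFrame | None = None
    insertion_truth: pd.DataFrame | None = None
    trajectory_truth: pd.Series | None = None


def _check_disjoint(regions: Sequence[PlantedRegion], what: str) -> None:
    by_chrom: dict[str, list[PlantedRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping planted {what} regions: {a.id} and {b.id}"
                )


def generate_methylome(
    genome: GenomeSpec,
    baselines: Mapping[str, float],
    planted: Sequence[PlantedRegion] = (),
    coverage: float = 30.0,
    nonconversion: float = 0.005,
    mca_baselines: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[dict[str, MethylomeTable], PlantedTruth]:
    """Simulate per-cytosine call tables for several sample groups.

    Parameters
    ----------
    baselines
        Group name -> genome-wide true mCG level outside planted regions
        (e.g. ``{"fibroblast": 0.75, "hES": 0.82, "primed-hiPS": 0.80}``).
    planted
        Planted regions; CG-affecting kinds (dmr/pmd/icr) must be mutually
        disjoint, as must CH-DMRs.
    coverage
        Mean per-site read depth; per-site depth is Poisson(coverage),
        floored at 1 inside planted regions, sites with depth 0 dropped.
    nonconversion
        Bisulfite non-conversion rate in [0, 0.05]: an unmethylated cytosine
        is read as methylated with this probability.  The spike-in contig is
        truly unmethylated, so its observed level estimates this rate.
    mca_baselines
        Group -> true mCA level outside CH-DMRs (default 0.05 everywhere).
    """
    if not 0 <= nonconversion <= 0.05:
        raise ValueError("nonconversion must be in [0, 0.05]")
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    for g, b in baselines.items():
        if not 0 <= b <= 1:
            raise ValueError(f"baseline for {g!r} outside [0,1]")
    cg_planted = [r for r in planted if r.kind in ("dmr", "pmd", "icr")]
    ch_planted = [r for r in planted if r.kind == "chdmr"]
    _check_disjoint(cg_planted, "CG")
    _check_disjoint(ch_planted, "CH")
    sizes = genome.sizes
    for r in planted:
        if r.chrom not in sizes or r.end > sizes[r.chrom] or r.start < 0:
            raise ValueError(f"planted region {r.id} outside its contig")

    mca_baselines = dict(mca_baselines or {})
    rng = np.random.default_rng(seed)
    tables: dict[str, MethylomeTable] = {}

    # site map shared by all groups: per contig, tiles of 100 bp
    site_frames = []
    for chrom, length in genome.contigs:
        tiles = np.arange(0, length - _TILE + 1, _TILE, dtype=np.int64)
        for offset, strand, context, dinuc in (
            (_CG_OFFSET, "+", "CG", "CG"),
            (_CG_OFFSET + 1, "-", "CG", "CG"),
            (_CA_OFFSETS[0], "+", "CHH", "CA"),
            (_CA_OFFSETS[1], "+", "CHH", "CA"),
            (_CT_OFFSET, "+", "CHH", "CT"),
        ):
            site_frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": tiles + offset,
                        "strand": strand,
                        "context": context,
                        "dinucleotide": dinuc,
                    }
                )
            )
    sites = pd.concat(site_frames, ignore_index=True)
    is_spike = (sites["chrom"] == genome.spike_in_contig).to_numpy()
    is_cg = (sites["context"] == "CG").to_numpy()
    is_ca = (sites["dinucleotide"] == "CA").to_numpy()
    pos0 = (sites["pos"] - 1).to_numpy()  # 0-based coordinate of the site
    chrom_arr = sites["chrom"].to_numpy()

    in_planted = np.zeros(len(sites), dtype=bool)

    def region_mask(r: PlantedRegion) -> np.ndarray:
        return (chrom_arr == r.chrom) & (pos0 >= r.start) & (pos0 < r.end)

    masks = {r.id: region_mask(r) for r in planted}
    for m in masks.values():
        in_planted |= m

    for group in baselines:
        true = np.where(is_cg, baselines[group], 0.0)
        mca = mca_baselines.get(group, 0.05)
        true = np.where(~is_cg, np.where(is_ca, mca, mca / 2), true)
        for r in cg_planted:
            if group in r.levels:
                true = np.where(masks[r.id] & is_cg, r.levels[group], true)
            elif r.kind == "icr":
                true = np.where(masks[r.id] & is_cg, 0.5, true)
        for r in ch_planted:
            if group in r.levels:
                true = np.where(masks[r.id] & is_ca, r.levels[group], true)
        true = np.where(is_spike, 0.0, true)
        p_obs = true + (1.0 - true) * nonconversion
        cov = rng.poisson(coverage, size=len(sites))
        cov = np.where(in_planted | is_spike, np.maximum(cov, 1), cov)
        keep = cov > 0
        mc = rng.binomial(cov[keep], p_obs[keep])
        df = sites.loc[keep].copy()
        df["mc"] = mc
        df["cov"] = cov[keep]
        tables[group] = MethylomeTable(
            df,
            sample_id=group,
            nonconversion={"CH": nonconversion, "CA": nonconversion, "CT": nonconversion},
            validate=False,
        )

    truth = PlantedTruth()
    dmrs = [r for r in planted if r.kind == "dmr"]
    if dmrs:
        rows = []
        for r in dmrs:
            row = {"id": r.id, "chrom": r.chrom, "start": r.start, "end": r.end, "label": r.label}
            for g, lv in r.levels.items():
                row[f"level_{g}"] = lv
            rows.append(row)
        truth.dmr_truth = pd.DataFrame(rows).set_index("id")
    for kind in ("pmd", "chdmr", "icr"):
        rs = [r for r in planted if r.kind == kind]
        if rs:
            truth.domain_truth[kind] = RegionSet.from_records(
                [r.to_interval() for r in rs], name=kind, ids=[r.id for r in rs]
            )
    icrs = [r for r in planted if r.kind == "icr"]
    if icrs:
        truth.icr_truth = pd.DataFrame(
            {
                "id": [r.id for r in icrs],
                "true_level": [r.levels.get("*", 0.5) for r in icrs],
            }
        ).set_index("id")
    return tables, truth


def generate_read_level_calls(
    region_id: str,
    epiallele_fractions: tuple[float, float, float],
    n_reads: int,
    cpgs_per_read: int = 4,
    seed: int = 0,
) -> list[ReadCallRecord]:
    """Draw reads from the three epiallele archetypes of an imprinted locus.

    ``epiallele_fractions`` = (fully methylated, fully unmethylated, partial);
    partial reads carry at least one methylated and one unmethylated call.
    """
    p_meth, p_unmeth, p_partial = epiallele_fractions
    if not np.isclose(p_meth + p_unmeth + p_partial, 1.0):
        raise ValueError("epiallele fractions must sum to 1")
    if min(epiallele_fractions) < 0:
        raise ValueError("epiallele fractions must be non-negative")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if cpgs_per_read < 2 and p_partial > 0:
        raise ValueError("partial epialleles need >= 2 CpGs per read")
    rng = np.random.default_rng(seed)
    kinds = rng.choice(3, size=n_reads, p=[p_meth, p_unmeth, p_partial])
    records = []
    for i, kind in enumerate(kinds):
        if kind == 0:
            calls = (1,) * cpgs_per_read
        elif kind == 1:
            calls = (0,) * cpgs_per_read
        else:
            n_meth = int(rng.integers(1, cpgs_per_read))  # 1 .. k-1
            arr = np.zeros(cpgs_per_read, dtype=int)
            arr[rng.choice(cpgs_per_read, size=n_meth, replace=False)] = 1
            calls = tuple(arr)
        records.append(ReadCallRecord(read_id=f"read_{i}", region_id=region_id, calls=calls))
    return records


# ---------------------------------------------------------------------------
# feature tracks with controlled overlap enrichment


def _overlap_start_space(
    genome: GenomeSpec, query: RegionSet, width: int
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per contig: merged integer start-ranges [s0, s1) in which a feature of
    ``width`` overlaps the query, and the complementary non-overlap ranges.
    Start positions are restricted to [0, L - width]."""
    merged = query.merged()
    overlap: dict[str, np.ndarray] = {}
    complement: dict[str, np.ndarray] = {}
    for chrom, length in genome.contigs:
        max_start = length - width
        if max_start < 0:
            overlap[chrom] = np.empty((0, 2), dtype=np.int64)
            complement[chrom] = np.empty((0, 2), dtype=np.int64)
            continue
        segs = []
        for s, e in merged.get(chrom, np.empty((0, 2), dtype=np.int64)):
            lo = max(0, s - width + 1)
            hi = min(max_start + 1, e)
            if lo < hi:
                segs.append((lo, hi))
        # merge (query merge can still leave touching segments after expansion)
        segs.sort()
        osegs: list[list[int]] = []
        for lo, hi in segs:
            if osegs and lo <= osegs[-1][1]:
                osegs[-1][1] = max(osegs[-1][1], hi)
            else:
                osegs.append([lo, hi])
        overlap[chrom] = np.asarray(osegs, dtype=np.int64).reshape(-1, 2)
        comp = []
        prev = 0
        for lo, hi in osegs:
            if prev < lo:
                comp.append((prev, lo))
            prev = hi
        if prev < max_start + 1:
            comp.append((prev, max_start + 1))
        complement[chrom] = np.asarray(comp, dtype=np.int64).reshape(-1, 2)
    return overlap, complement


def _sample_from_segments(
    segments: dict[str, np.ndarray], n: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Sample n integer starts uniformly from a per-chromosome segment union."""
    chroms, seg_list, lens = [], [], []
    for chrom, segs in segments.items():
        for s0, s1 in segs:
            chroms.append(chrom)
            seg_list.append((int(s0), int(s1)))
            lens.append(int(s1 - s0))
    total = sum(lens)
    if total == 0:
        raise ValueError("empty placement space")
    cum = np.concatenate([[0], np.cumsum(lens)])
    u = rng.integers(0, total, size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    return [(chroms[i], seg_list[i][0] + int(u[j] - cum[i])) for j, i in enumerate(idx)]


def generate_feature_tracks(
    genome: GenomeSpec,
    query: RegionSet,
    fold_enrichment: float = 1.0,
    feature_width_bp: int = 1000,
    n_features: int = 500,
    seed: int = 0,
    name: str = "features",
) -> RegionSet:
    """Place ``n_features`` intervals with a controlled enrichment of overlap
    with ``query``.

    Each feature independently overlaps the query with probability
    ``fold_enrichment * p0`` where ``p0`` is the overlap probability of a
    uniformly placed feature, so ``fold_enrichment = 1`` is exactly uniform
    placement (a calibrated null) and larger folds scale the expected overlap
    count linearly.  Features are placed on non-spike-in contigs only.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if fold_enrichment < 0:
        raise ValueError("fold_enrichment must be >= 0")
    rng = np.random.default_rng(seed)
    sub_genome = GenomeSpec(
        contigs=genome.contigs, spike_in_contig=genome.spike_in_contig, seed=genome.seed
    )
    overlap, complement = _overlap_start_space(sub_genome, query, feature_width_bp)
    # restrict to non-spike-in contigs
    overlap = {c: v for c, v in overlap.items() if c != genome.spike_in_contig}
    complement = {c: v for c, v in complement.items() if c != genome.spike_in_contig}
    n_over = sum(int((s[:, 1] - s[:, 0]).sum()) for s in overlap.values())
    n_comp = sum(int((s[:, 1] - s[:, 0]).sum()) for s in complement.values())
    p0 = n_over / (n_over + n_comp)
    q = fold_enrichment * p0
    if q > 1:
        raise ValueError(
            f"fold_enrichment {fold_enrichment} demands overlap probability {q:.3f} > 1; "
            "not enough overlapping placements exist"
        )
    hit = rng.random(n_features) < q
    placements: list[tuple[str, int]] = [("", 0)] * n_features
    n_hit = int(hit.sum())
    if n_hit:
        for i, pl in zip(np.flatnonzero(hit), _sample_from_segments(overlap, n_hit, rng)):
            placements[i] = pl
    if n_features - n_hit:
        for i, pl in zip(
            np.flatnonzero(~hit), _sample_from_segments(complement, n_features - n_hit, rng)
        ):
            placements[i] = pl
    df = pd.DataFrame(
        {
            "chrom": [c for c, _ in placements],
            "start": [s for _, s in placements],
            "end": [s + feature_width_bp for _, s in placements],
            "id": [f"{name}_{i}" for i in range(n_features)],
        }
    )
    return RegionSet(df, name=name)


# ---------------------------------------------------------------------------
# Cas9-enrichment insertion-read libraries

ALIGNMENT_PAIR_COLUMNS = [
    "read_id",
    "chrom",
    "g_start",
    "g_end",
    "strand",
    "mapq",
    "is_primary",
    "g_read_start",
    "g_read_end",
    "v_start",
    "v_end",
    "v_read_start",
    "v_read_end",
    "read_length",
]


def generate_insertion_library(
    n_true_sites: int,
    mean_reads_per_site: float,
    genome: GenomeSpec,
    vector_length_bp: int = 8000,
    noise_spec: Mapping[str, float] | None = None,
    seed: int = 0,
    site_jitter_bp: int = 10,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate the alignment-pair table of a Cas9-enrichment nanopore run.

    ``n_true_sites`` insertion loci are placed on a 1-kb grid across the
    non-spike-in contigs; per-site read counts are Poisson(``mean_reads_per_site``)
    (sites drawing 0 reads are unobserved but remain in the truth).  Each good
    read carries a genome alignment and a vector alignment that are adjacent
    on the read; the genome-side junction coordinate equals the true site up
    to ``site_jitter_bp``.  ``noise_spec`` maps filter names
    (``non_primary, short, low_mapq, gap, single_mapped``) to the fraction of
    additional reads violating exactly that one criterion.
    """
    if n_true_sites < 1:
        raise ValueError("n_true_sites must be >= 1")
    if mean_reads_per_site <= 0:
        raise ValueError("mean_reads_per_site must be > 0")
    noise_spec = dict(noise_spec or {})
    unknown = set(noise_spec) - {"non_primary", "short", "low_mapq", "gap", "single_mapped"}
    if unknown:
        raise ValueError(f"unknown noise criteria: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    grid = 1000
    margin = 5000
    candidates: list[tuple[str, int]] = []
    for chrom, length in genome.autosomal_contigs:
        for p in range(margin, length - margin, grid):
            candidates.append((chrom, p))
    if len(candidates) < n_true_sites:
        raise ValueError("genome too small for the requested number of insertion sites")
    pick = rng.choice(len(candidates), size=n_true_sites, replace=False)
    sites = [candidates[i] for i in sorted(pick)]
    reads_per_site = rng.poisson(mean_reads_per_site, size=n_true_sites)

    rows: list[dict] = []
    counter = itertools.count()

    def make_read(chrom: str, site: int, violate: str | None) -> dict:
        glen = int(rng.integers(1000, 3001))
        gap = int(rng.integers(0, 11))
        vlen = int(rng.integers(500, min(vector_length_bp, 1500) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        vector_right = rng.random() < 0.5
        mapq, primary = 60, True
        junction = site + int(rng.integers(-site_jitter_bp, site_jitter_bp + 1))
        if violate == "short":
            glen = int(rng.integers(200, 800))  # < 800 bp
        elif violate == "low_mapq":
            mapq = int(rng.integers(0, 60))
        elif violate == "non_primary":
            primary = False
        elif violate == "gap":
            gap = int(rng.integers(51, 200))
        # genome coordinates such that the boundary adjacent to the vector
        # junction on the read equals `junction`
        if (vector_right and strand == "+") or (not vector_right and strand == "-"):
            g_start, g_end = junction - glen, junction
        else:
            g_start, g_end = junction, junction + glen
        if vector_right:
            g_read = (0, glen)
            v_read = (glen + gap, glen + gap + vlen)
        else:
            v_read = (0, vlen)
            g_read = (vlen + gap, vlen + gap + glen)
        read_length = glen + gap + vlen
        v_start = int(rng.integers(0, vector_length_bp - vlen + 1))
        row = {
            "read_id": f"read_{next(counter)}",
            "chrom": chrom,
            "g_start": g_start,
            "g_end": g_end,
            "strand": strand,
            "mapq": mapq,
            "is_primary": primary,
            "g_read_start": g_read[0],
            "g_read_end": g_read[1],
            "v_start": v_start,
            "v_end": v_start + vlen,
            "v_read_start": v_read[0],
            "v_read_end": v_read[1],
            "read_length": read_length,
        }
        if violate == "single_mapped":
            for k in ("v_start", "v_end", "v_read_start", "v_read_end"):
                row[k] = np.nan
        return row

    for (chrom, site), n_reads in zip(sites, reads_per_site):
        for _ in range(int(n_reads)):
            rows.append(make_read(chrom, site, violate=None))
    n_good = len(rows)
    for criterion, frac in noise_spec.items():
        for _ in range(int(round(frac * n_good))):
            chrom, site = sites[int(rng.integers(0, n_true_sites))]
            rows.append(make_read(chrom, site, violate=criterion))

    table = pd.DataFrame(rows, columns=ALIGNMENT_PAIR_COLUMNS)
    truth = PlantedTruth(
        insertion_truth=pd.DataFrame(
            {
                "chrom": [c for c, _ in sites],
                "pos": [p for _, p in sites],
                "n_reads": reads_per_site,
            }
        )
    )
    return table, truth


def generate_trajectories(
    n_elements: int,
    timepoints: Sequence[str],
    cluster_centroids: np.ndarray,
    noise_sd: float = 0.03,
    background_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Element x time-point methylation matrix with planted cluster structure.

    Cluster members are their centroid plus Gaussian noise, clipped to [0,1];
    background elements are flat trajectories with range < 0.2 (uniform level
    plus small jitter), labelled ``-1`` in the truth.
    """
    centroids = np.asarray(cluster_centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[1] != len(timepoints):
        raise ValueError("cluster_centroids must be (k, n_timepoints)")
    if centroids.min() < 0 or centroids.max() > 1:
        raise ValueError("centroid values must lie in [0,1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= background_fraction < 1:
        raise ValueError("background_fraction must be in [0,1)")
    rng = np.random.default_rng(seed)
    k = centroids.shape[0]
    n_bg = int(round(background_fraction * n_elements))
    n_mem = n_elements - n_bg
    labels = np.concatenate([np.arange(n_mem) % k, np.full(n_bg, -1)])
    values = np.empty((n_elements, len(timepoints)))
    for i, lab in enumerate(labels):
        if lab >= 0:
            values[i] = centroids[lab] + rng.normal(0, noise_sd, size=len(timepoints))
        else:
            level = rng.uniform(0.25, 0.75)
            values[i] = level + rng.uniform(-0.05, 0.05, size=len(timepoints))
    values = np.clip(values, 0, 1)
    ids = [f"elem_{i:05d}" for i in range(n_elements)]
    matrix = pd.DataFrame(values, index=ids, columns=list(timepoints))
    truth = PlantedTruth(trajectory_truth=pd.Series(labels, index=ids, name="cluster"))
    return matrix, truth
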
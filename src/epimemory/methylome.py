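"""Coverage-weighted methylation statistics from per-cytosine call tables.

The methylation level of a region is the coverage-weighted mean: the sum of
methylated C calls (mC) over all cytosines of the requested context inside the
region, divided by the total number of informative (C-or-T) calls — mCG/CG,
mCA/CA, mCH/CH.  For non-CG contexts the bisulfite non-conversion rate
measured on an unmethylated spike-in genome is subtracted (floored at 0),
because incomplete conversion inflates the tiny mCH signal far more than the
large mCG signal.

All functions treat a region with zero covered sites as *undefined* (NaN),
never as 0, so downstream differences cannot fabricate signal from missing
coverage.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import MethylomeTable, ReadCallRecord, RegionSet, warn_if_uncollapsed

__all__ = [
    "collapse_cg_strands",
    "weighted_methylation",
    "nonconversion_rate",
    "sliding_window_track",
    "classify_read",
    "classify_reads",
]


def collapse_cg_strands(table: MethylomeTable) -> MethylomeTable:
    """Merge symmetric CG calls from the two strands into one record.

    A plus-strand CG at position ``p`` and the minus-strand CG at ``p + 1``
    report the same CpG dinucleotide; their ``mc`` and ``cov`` are summed into
    a single plus-strand record at ``p``.  Unpaired CG calls are kept as-is
    (minus-strand singletons are re-anchored to the plus-strand position so
    the output is unstranded); non-CG contexts pass through unchanged.
    Total mc and cov are conserved.
    """
    df = table.df
    cg = df[df["context"] == "CG"]
    rest = df[df["context"] != "CG"]
    if len(cg) == 0:
        out = df.copy()
    else:
        anchored = cg.copy()
        # anchor both strands at the plus-strand C of the CpG
        anchored["pos"] = np.where(anchored["strand"] == "-", anchored["pos"] - 1, anchored["pos"])
        grouped = (
            anchored.groupby(["chrom", "pos"], as_index=False, sort=False)
            .agg(mc=("mc", "sum"), cov=("cov", "sum"))
        )
        grouped["strand"] = "+"
        grouped["context"] = "CG"
        grouped["dinucleotide"] = "CG"
        out = pd.concat([grouped, rest], ignore_index=True)
    return MethylomeTable(
        out, sample_id=table.sample_id, nonconversion=table.nonconversion, validate=False
    )


def _region_sums(
    table: MethylomeTable, regions: RegionSet, context: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region (sum mc, sum cov) over sites of ``context``; vectorized via
    searchsorted on the sorted site positions of each chromosome."""
    mask = table.context_mask(context)
    sub = table.df.loc[mask, ["chrom", "pos", "mc", "cov"]]
    n = len(regions)
    mc_out = np.zeros(n, dtype=np.float64)
    cov_out = np.zeros(n, dtype=np.float64)
    by_chrom = {str(c): g for c, g in sub.groupby("chrom", sort=False)}
    rdf = regions.df
    for chrom, g in rdf.groupby("chrom", sort=False):
        sites = by_chrom.get(str(chrom))
        if sites is None:
            continue
        pos = sites["pos"].to_numpy()
        cmc = np.concatenate([[0], np.cumsum(sites["mc"].to_numpy(dtype=np.int64))])
        ccov = np.concatenate([[0], np.cumsum(sites["cov"].to_numpy(dtype=np.int64))])
        # site at 1-based pos is in [start, end) iff start < pos <= end
        lo = np.searchsorted(pos, g["start"].to_numpy() + 1, side="left")
        hi = np.searchsorted(pos, g["end"].to_numpy(), side="right")
        idx = g.index.to_numpy()
        mc_out[rdf.index.get_indexer(idx)] = cmc[hi] - cmc[lo]
        cov_out[rdf.index.get_indexer(idx)] = ccov[hi] - ccov[lo]
    return mc_out, cov_out


def weighted_methylation(
    table: MethylomeTable,
    regions: RegionSet,
    context: str = "CG",
    subtract_nonconversion: bool | None = None,
) -> pd.Series:
    """Per-region coverage-weighted methylation level (sum mc / sum cov).

    Returns a Series indexed by region id, values in [0, 1] or NaN for regions
    with no covered site of the context.  For CH/CA/CT/CC the context-specific
    non-conversion rate stored on the table is subtracted and the result
    floored at 0; CG is never corrected.
    """
    if not table.context_mask(context).any():
        raise ValueError(f"no calls of context {context!r} in table {table.sample_id!r}")
    if context == "CG":
        warn_if_uncollapsed(table)
    mc, cov = _region_sums(table, regions, context)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(cov > 0, mc / np.where(cov > 0, cov, 1), np.nan)
    if subtract_nonconversion is None:
        subtract_nonconversion = context != "CG"
    if subtract_nonconversion and context != "CG":
        nc = table.nonconversion_for(context)
        level = np.where(np.isnan(level), np.nan, np.maximum(level - nc, 0.0))
    return pd.Series(level, index=regions.df["id"].to_numpy(), name=f"m{context}")


def nonconversion_rate(table: MethylomeTable, spike_in_contig: str, context: str = "CH") -> float:
    """Bisulfite non-conversion rate: the coverage-weighted apparent methylation
    of the unmethylated spike-in contig for the given context."""
    mask = (table.df["chrom"] == spike_in_contig) & table.context_mask(context)
    sub = table.df.loc[mask]
    if len(sub) == 0:
        raise ValueError(
            f"spike-in contig {spike_in_contig!r} has no covered {context} sites"
        )
    return float(sub["mc"].sum() / sub["cov"].sum())


def sliding_window_track(
    table: MethylomeTable,
    chrom_sizes: dict[str, int],
    context: str = "CA",
    window_bp: int = 5000,
    step_bp: int = 1000,
) -> pd.DataFrame:
    """Sliding-window methylation track (default 5-kb windows, 1-kb slide).

    Windows tile each contig from 0 and are emitted only if fully contained in
    the contig; a window appears in the output only when it covers >= 1
    informative site.  The context non-conversion rate is subtracted from each
    window and floored at 0.  Returns a bedGraph-style frame
    ``chrom, start, end, value``.
    """
    mask = table.context_mask(context)
    sub = table.df.loc[mask, ["chrom", "pos", "mc", "cov"]]
    nc = table.nonconversion_for(context)
    frames = []
    for chrom, g in sub.groupby("chrom", sort=True):
        length = chrom_sizes.get(str(chrom))
        if length is None or length < window_bp:
            continue
        starts = np.arange(0, length - window_bp + 1, step_bp, dtype=np.int64)
        pos = g["pos"].to_numpy()
        cmc = np.concatenate([[0], np.cumsum(g["mc"].to_numpy(dtype=np.int64))])
        ccov = np.concatenate([[0], np.cumsum(g["cov"].to_numpy(dtype=np.int64))])
        lo = np.searchsorted(pos, starts + 1, side="left")
        hi = np.searchsorted(pos, starts + window_bp, side="right")
        mc = cmc[hi] - cmc[lo]
        cov = ccov[hi] - ccov[lo]
        keep = cov > 0
        value = np.maximum(mc[keep] / cov[keep] - nc, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": str(chrom),
                    "start": starts[keep],
                    "end": starts[keep] + window_bp,
                    "value": value,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    return pd.concat(frames, ignore_index=True)


def classify_read(calls: Sequence[int]) -> str:
    """Classify one read's CG calls: ``methylated`` if every CG position is
    called methylated, ``unmethylated`` if none is, ``partial`` if it carries
    at least one methylated and one unmethylated call."""
    if len(calls) == 0:
        raise ValueError("empty call list")
    s = sum(calls)
    if s == len(calls):
        return "methylated"
    if s == 0:
        return "unmethylated"
    return "partial"


def classify_reads(records: Iterable[ReadCallRecord]) -> pd.DataFrame:
    """Per-region counts of methylated / unmethylated / partial reads.

    Every record is assigned exactly one class, so the three counts partition
    the reads of each region.
    """
    counts: dict[str, Counter] = {}
    for rec in records:
        counts.setdefault(rec.region_id, Counter())[classify_read(rec.calls)] += 1
    out = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    for col in ("methylated", "unmethylated", "partial"):
        if col not in out.columns:
            out[col] = 0
    out = out[["methylated", "unmethylated", "partial"]]
    out.index.name = "region_id"
    return out.sort_index()
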
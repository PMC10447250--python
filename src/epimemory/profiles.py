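"""Flank-normalized binned methylation profiles over large domains.

For each domain (e.g. a megabase-scale non-CpG hypomethylated CH-DMR) the
domain body plus equal-length upstream and downstream flanks are each split
into 30 equal-length bins; coverage-weighted mCA/CA is computed per bin (with
non-conversion subtraction), and the 90 bin values of each region are divided
by their per-region maximum so every profile plateaus at 1 in its most
methylated bin.  Aggregating the normalized profiles across domains gives the
meta-profile curve: a non-CpG-methylation depleted domain shows body bins
below the flanking plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
import pandas as pd

from .methylome import weighted_methylation
from .types import MethylomeTable, RegionSet

__all__ = [
    "BinnedProfile",
    "bin_edges",
    "binned_profile",
    "flank_normalize",
    "aggregate_profiles",
    "domain_cg_summary",
]

N_BINS_DEFAULT = 30


@dataclass
class BinnedProfile:
    """90 bin values (upstream flank, body, downstream flank; 30 bins each)."""

    region_id: str
    bins: np.ndarray  # shape (3 * n_bins,), NaN = bin with no covered site
    n_bins: int = N_BINS_DEFAULT
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (3 * self.n_bins,):
            raise ValueError(f"expected {3 * self.n_bins} bin values")

    @property
    def upstream(self) -> np.ndarray:
        return self.bins[: self.n_bins]

    @property
    def body(self) -> np.ndarray:
        return self.bins[self.n_bins : 2 * self.n_bins]

    @property
    def downstream(self) -> np.ndarray:
        return self.bins[2 * self.n_bins :]


def bin_edges(start: int, end: int, n_bins: int) -> np.ndarray:
    """Split [start, end) into n_bins integer bins partitioning it exactly.

    The remainder ``r = (end - start) % n_bins`` is absorbed as one extra bp
    by the first ``r`` bins (deterministic).
    """
    length = end - start
    if length < n_bins:
        raise ValueError(f"region of length {length} cannot take {n_bins} bins")
    base, r = divmod(length, n_bins)
    widths = np.full(n_bins, base, dtype=np.int64)
    widths[:r] += 1
    return start + np.concatenate([[0], np.cumsum(widths)])


def binned_profile(
    table: MethylomeTable,
    domains: RegionSet,
    chrom_sizes: dict[str, int] | None = None,
    n_bins: int = N_BINS_DEFAULT,
    context: str = "CA",
) -> list[BinnedProfile]:
    """30-bin body + equal-length flank methylation profile per domain.

    Flanks have the same length as the body; a domain whose flanks do not fit
    inside its contig (when ``chrom_sizes`` is given) or whose body is shorter
    than ``n_bins`` bp is skipped with a warning.  Bin values are
    coverage-weighted levels with non-conversion subtraction (for non-CG
    contexts); bins with no covered site are NaN.
    """
    if not table.context_mask(context).any():
        raise ValueError(f"no calls of context {context!r} in table {table.sample_id!r}")
    profiles: list[BinnedProfile] = []
    bin_rows = []
    bin_ids = []
    for _, row in domains.df.iterrows():
        chrom, start, end, rid = row["chrom"], int(row["start"]), int(row["end"]), row["id"]
        length = end - start
        if length < n_bins:
            warnings.warn(f"domain {rid} shorter than {n_bins} bp; skipped")
            continue
        if start - length < 0 or (
            chrom_sizes is not None and end + length > chrom_sizes.get(str(chrom), np.inf)
        ):
            warnings.warn(f"domain {rid}: flanks do not fit the contig; skipped")
            continue
        edges = np.concatenate(
            [
                bin_edges(start - length, start, n_bins),
                bin_edges(start, end, n_bins)[1:],
                bin_edges(end, end + length, n_bins)[1:],
            ]
        )
        for b in range(3 * n_bins):
            bin_rows.append((chrom, int(edges[b]), int(edges[b + 1])))
            bin_ids.append(f"{rid}__{b}")
    if not bin_rows:
        return []
    bins_rs = RegionSet.from_records(bin_rows, name="bins", ids=bin_ids)
    levels = weighted_methylation(table, bins_rs, context=context)
    by_region: dict[str, np.ndarray] = {}
    for bid, val in levels.items():
        rid, b = bid.rsplit("__", 1)
        by_region.setdefault(rid, np.full(3 * n_bins, np.nan))[int(b)] = val
    for rid, vals in by_region.items():
        profiles.append(BinnedProfile(region_id=rid, bins=vals, n_bins=n_bins))
    return profiles


def flank_normalize(profile: BinnedProfile) -> BinnedProfile:
    """Divide every bin by the region's maximum bin value (max becomes 1).

    Normalizing an already normalized profile is a no-op (idempotent).
    """
    finite = profile.bins[np.isfinite(profile.bins)]
    if finite.size == 0 or finite.max() <= 0:
        raise ValueError(
            f"profile {profile.region_id}: no positive bin to normalize against"
        )
    return BinnedProfile(
        region_id=profile.region_id,
        bins=profile.bins / finite.max(),
        n_bins=profile.n_bins,
        normalized=True,
    )


def aggregate_profiles(profiles: list[BinnedProfile]) -> pd.DataFrame:
    """Per-bin mean curve over regions (NaN bins excluded pairwise).

    Returns a frame with columns ``mean`` and ``n`` (regions contributing to
    each bin), indexed 0..3*n_bins-1.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    n_bins = profiles[0].n_bins
    stack = np.vstack([p.bins for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(stack, axis=0)
    n = np.isfinite(stack).sum(axis=0)
    return pd.DataFrame({"mean": mean, "n": n}, index=pd.RangeIndex(3 * n_bins, name="bin"))


def domain_cg_summary(table: MethylomeTable, domains: RegionSet) -> pd.Series:
    """Per-domain coverage-weighted mCG/CG (NaN when a domain has no CG site).

    Used to inspect partial CG methylation of PMDs and CH-DMR bodies; for a
    flank-normalized CG variant reuse :func:`binned_profile` with
    ``context="CG"``.
    """
    return weighted_methylation(table, domains, context="CG")
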
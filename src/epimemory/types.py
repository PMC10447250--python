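"""Core domain types shared across the package.

Coordinate conventions (used everywhere, converted only at I/O boundaries):

* Per-cytosine positions are **1-based** (CGmap convention).
* Genomic intervals are **0-based half-open** (BED convention).
* A cytosine at 1-based position ``pos`` lies inside the interval
  ``[start, end)`` iff ``start < pos <= end``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Valid methylation contexts for a cytosine call (CGmap vocabulary).
CONTEXTS = ("CG", "CHG", "CHH")

#: Columns of the per-cytosine call table wrapped by :class:`MethylomeTable`.
CALL_COLUMNS = ("chrom", "pos", "strand", "context", "dinucleotide", "mc", "cov")

#: Columns of a region table wrapped by :class:`RegionSet` (BED-like).
REGION_COLUMNS = ("chrom", "start", "end")


@dataclass(frozen=True)
class GenomeSpec:
    """A synthetic genome: named contigs plus an unmethylated spike-in contig.

    The spike-in plays the role of the unmethylated control genome added to
    bisulfite libraries to measure the non-conversion rate; its cytosines are
    truly unmethylated so any apparent methylation is conversion failure.
    """

    contigs: tuple[tuple[str, int], ...]
    spike_in_contig: str | None = "spike"
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c for c, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        for name, length in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")
        if self.spike_in_contig is not None and self.spike_in_contig not in names:
            raise ValueError(f"spike-in contig {self.spike_in_contig!r} not in contigs")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.contigs)

    @property
    def autosomal_contigs(self) -> tuple[tuple[str, int], ...]:
        """Contigs excluding the spike-in control."""
        return tuple((c, l) for c, l in self.contigs if c != self.spike_in_contig)


@dataclass(frozen=True)
class CytosineCall:
    """One cytosine with methylated-call count ``mc`` out of ``cov`` informative reads."""

    chrom: str
    pos: int
    strand: str
    context: str
    dinucleotide: str
    mc: int
    cov: int

    def __post_init__(self) -> None:
        if not (0 <= self.mc <= self.cov):
            raise ValueError(f"require 0 <= mc <= cov, got mc={self.mc} cov={self.cov}")
        if self.cov <= 0:
            raise ValueError("cov must be positive")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")


class MethylomeTable:
    """Per-cytosine methylation calls for one sample.

    Thin wrapper around a :class:`pandas.DataFrame` with columns
    ``chrom, pos, strand, context, dinucleotide, mc, cov`` sorted by
    ``(chrom, pos, strand)``.  ``nonconversion`` optionally maps a context
    (or dinucleotide, e.g. ``"CA"``) to the bisulfite non-conversion rate
    measured on the spike-in control.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        sample_id: str = "sample",
        nonconversion: Mapping[str, float] | None = None,
        validate: bool = True,
    ) -> None:
        df = df.loc[:, list(CALL_COLUMNS)].copy()
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
        if validate:
            if (df["mc"] > df["cov"]).any():
                bad = df.index[(df["mc"] > df["cov"])][0]
                raise ValueError(f"mc > cov at row {bad}")
            if (df["cov"] <= 0).any():
                raise ValueError("cov must be positive for every call")
            dup = df.duplicated(["chrom", "pos", "strand"])
            if dup.any():
                raise ValueError("duplicate (chrom, pos, strand) rows")
        self.df = df
        self.sample_id = sample_id
        self.nonconversion: dict[str, float] = dict(nonconversion or {})
        self.n_malformed = 0  # set by readers that skipped rows

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"MethylomeTable({self.sample_id!r}, {len(self)} calls)"

    def context_mask(self, context: str) -> pd.Series:
        """Boolean mask selecting calls of a (possibly composite) context.

        ``CG`` / ``CHG`` / ``CHH`` select on the context column; ``CH`` selects
        every non-CG call; ``CA`` / ``CT`` / ``CC`` select on the dinucleotide.
        """
        if context in CONTEXTS:
            return self.df["context"] == context
        if context == "CH":
            return self.df["context"] != "CG"
        if context in ("CA", "CT", "CC"):
            return self.df["dinucleotide"] == context
        raise ValueError(f"unknown context {context!r}")

    def nonconversion_for(self, context: str) -> float:
        """Non-conversion rate to subtract for ``context`` (0 for CG, which is
        never corrected; falls back to the generic CH rate when the specific
        dinucleotide rate is absent)."""
        if context == "CG":
            return 0.0
        if context in self.nonconversion:
            return float(self.nonconversion[context])
        return float(self.nonconversion.get("CH", 0.0))


class RegionSet:
    """A named set of genomic intervals with BED semantics (0-based half-open).

    Wraps a DataFrame with at least ``chrom, start, end``; optional ``id``,
    ``score`` and ``strand`` columns are preserved.
    """

    def __init__(self, df: pd.DataFrame, name: str = "regions", validate: bool = True) -> None:
        cols = [c for c in ("chrom", "start", "end", "id", "score", "strand") if c in df.columns]
        df = df.loc[:, cols].copy()
        if "id" not in df.columns:
            df["id"] = [f"{name}_{i}" for i in range(len(df))]
        if validate:
            if (df["start"] >= df["end"]).any():
                raise ValueError("every interval must satisfy start < end")
            if df["id"].duplicated().any():
                raise ValueError("interval ids must be unique")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.name = name

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        name: str = "regions",
        ids: Sequence[str] | None = None,
    ) -> "RegionSet":
        df = pd.DataFrame(list(records), columns=["chrom", "start", "end"])
        if ids is not None:
            df["id"] = list(ids)
        return cls(df, name=name)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"RegionSet({self.name!r}, {len(self)} intervals)"

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.df.groupby("chrom", sort=True)}

    def merged(self) -> dict[str, np.ndarray]:
        """Per-chromosome merged intervals as an (n, 2) array of start/end."""
        out: dict[str, np.ndarray] = {}
        for chrom, g in self.df.groupby("chrom", sort=True):
            ivals = g[["start", "end"]].to_numpy()
            ivals = ivals[np.argsort(ivals[:, 0], kind="mergesort")]
            merged: list[list[int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([int(s), int(e)])
            out[str(chrom)] = np.asarray(merged, dtype=np.int64)
        return out


@dataclass
class ReadCallRecord:
    """Ordered CG methylation calls (1 = methylated, 0 = unmethylated) on one read."""

    read_id: str
    region_id: str
    calls: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.calls) == 0:
            raise ValueError("a read record needs at least one CG call")
        if any(c not in (0, 1) for c in self.calls):
            raise ValueError("calls must be 0/1")


def check_uncollapsed_cg(table: MethylomeTable) -> bool:
    """Heuristic: does the table still contain stranded (uncollapsed) CG calls?

    True when any minus-strand CG call is present.
    """
    cg = table.df[table.df["context"] == "CG"]
    return bool((cg["strand"] == "-").any())


def warn_if_uncollapsed(table: MethylomeTable) -> None:
    if check_uncollapsed_cg(table):
        warnings.warn(
            "CG calls appear stranded (minus-strand records present); "
            "collapse_cg_strands() is recommended before computing CG levels",
            stacklevel=3,
        )
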
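"""Readers and writers for the plain-text formats the pipeline consumes.

Supported dialects
------------------
``cgmap``
    The 8-column CGmap TSV produced by base-resolution bisulfite callers:
    ``chrom  nucleotide  pos  context  dinucleotide  level  mc  cov`` with
    1-based positions; ``nucleotide`` C means the call is on the plus strand,
    G the minus strand.
``bedgraph_counts``
    A bedGraph-style TSV extended with counts, fixed here as
    ``chrom  start  end  level  mc  cov`` (0-based half-open, one cytosine per
    row).  bedGraph proper has no count columns, and this dialect carries no
    strand or context either: rows are taken as strand-collapsed CG calls.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .types import CONTEXTS, MethylomeTable, RegionSet

_CGMAP_COLS = ["chrom", "nucleotide", "pos", "context", "dinucleotide", "level", "mc", "cov"]
_BGC_COLS = ["chrom", "start", "end", "level", "mc", "cov"]


def read_cytosine_calls(
    path: str | Path,
    dialect: str = "cgmap",
    sample_id: str | None = None,
    nonconversion: Mapping[str, float] | None = None,
) -> MethylomeTable:
    """Read a per-cytosine methylation call file into a :class:`MethylomeTable`.

    Malformed rows (wrong field count, unparseable numbers, unknown context)
    are skipped and counted in ``table.n_malformed``; a row with ``mc > cov``
    is a hard error naming the offending line.
    """
    path = Path(path)
    if dialect not in ("cgmap", "bedgraph_counts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[tuple] = []
    n_malformed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "cgmap":
                    chrom, nuc, pos, context, dinuc, _level, mc, cov = fields
                    if context not in CONTEXTS or nuc not in ("C", "G"):
                        raise ValueError
                    strand = "+" if nuc == "C" else "-"
                    row = (chrom, int(pos), strand, context, dinuc, int(mc), int(cov))
                else:
                    chrom, start, _end, _level, mc, cov = fields
                    row = (chrom, int(start) + 1, ".", "CG", "CG", int(mc), int(cov))
            except ValueError:
                n_malformed += 1
                continue
            if row[5] > row[6]:
                raise ValueError(f"{path.name} line {lineno}: mc={row[5]} exceeds cov={row[6]}")
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "dinucleotide", "mc", "cov"])
    table = MethylomeTable(df, sample_id=sample_id or path.stem, nonconversion=nonconversion)
    table.n_malformed = n_malformed
    return table


def write_cytosine_calls(table: MethylomeTable, path: str | Path, dialect: str = "cgmap") -> None:
    """Write a call table in the given dialect (inverse of :func:`read_cytosine_calls`)."""
    df = table.df
    with np.errstate(invalid="ignore"):
        level = df["mc"] / df["cov"]
    if dialect == "cgmap":
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "nucleotide": np.where(df["strand"] == "-", "G", "C"),
                "pos": df["pos"],
                "context": df["context"],
                "dinucleotide": df["dinucleotide"],
                "level": level.round(6),
                "mc": df["mc"],
                "cov": df["cov"],
            }
        )
    elif dialect == "bedgraph_counts":
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"] - 1,
                "end": df["pos"],
                "level": level.round(6),
                "mc": df["mc"],
                "cov": df["cov"],
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read BED3/BED6 into a :class:`RegionSet` (extra columns ignored)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    cols = ["chrom", "start", "end", "id", "score", "strand"][: min(ncol, 6)]
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    return RegionSet(df, name=name or path.stem)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    df = regions.df
    cols = ["chrom", "start", "end", "id"]
    out = df[cols].copy()
    out["score"] = df["score"] if "score" in df.columns else 0
    out["strand"] = df["strand"] if "strand" in df.columns else "."
    out.to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom\tsize`` TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(sorted(sizes.items())).to_csv(path, sep="\t", header=False, index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read an element x column TSV matrix with a header row and index column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
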
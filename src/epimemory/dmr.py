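"""Classify CG-DMRs into epigenetic-memory and aberrant-methylation classes.

A DMR between an induced pluripotent stem (hiPS) cell line and embryonic stem
(hES) cells is placed in the two-delta plane:

* ``delta_es``  = hiPS level - hES level
* ``delta_fib`` = hiPS level - fibroblast (cell-of-origin) level

With classification threshold ``t`` (default 0.2 mCG/CG difference):

===================  ==============================  ============================
condition on Δes     condition on Δfib               label
===================  ==============================  ============================
|Δes| <= t           any                             below_threshold
Δes < -t (hypo)      |Δfib| <= t                     memory
Δes < -t             Δfib > t                        partial_memory
Δes < -t             Δfib < -t                       aberrant_hypo
Δes > t (hyper)      Δfib > t                        aberrant_hyper
Δes > t              |Δfib| <= t                     memory_hyper
Δes > t              Δfib < -t                       partial_hyper
===================  ==============================  ============================

"memory" means the hiPS line retained the somatic methylation state of its
cell of origin; "aberrant" means it acquired a state matching neither the
origin cell nor hES cells.  Equality with the threshold is assigned to the
no-difference side, and correction requires a difference strictly below the
threshold, so boundary behaviour is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylome import weighted_methylation
from .types import MethylomeTable, RegionSet

__all__ = [
    "CLASS_LABELS",
    "ClassificationConfig",
    "filter_candidate_dmrs",
    "classify_dmr",
    "classify_dmr_set",
    "assess_correction",
    "timecourse_delta",
    "icr_screen",
]

CLASS_LABELS = (
    "memory",
    "partial_memory",
    "aberrant_hypo",
    "aberrant_hyper",
    "memory_hyper",
    "partial_hyper",
    "below_threshold",
)


@dataclass(frozen=True)
class ClassificationConfig:
    """Threshold on the mCG/CG difference used for all class boundaries."""

    threshold: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0,1)")


def filter_candidate_dmrs(
    raw_dmrs: pd.DataFrame,
    min_abs_diff: float = 0.2,
    max_p: float = 0.05,
    name: str = "dmrs",
) -> tuple[RegionSet, dict[str, int]]:
    """Filter candidate DMRs from an upstream detector.

    Keeps intervals with |methylation difference| strictly > ``min_abs_diff``
    and p-value strictly < ``max_p``.  ``raw_dmrs`` needs columns
    ``chrom, start, end, diff, p``.  Returns the retained regions plus counts
    of how many candidates each criterion dropped.
    """
    for col in ("chrom", "start", "end", "diff", "p"):
        if col not in raw_dmrs.columns:
            raise ValueError(f"raw DMR table lacks required column {col!r}")
    pass_diff = raw_dmrs["diff"].abs() > min_abs_diff
    pass_p = raw_dmrs["p"] < max_p
    kept = raw_dmrs[pass_diff & pass_p]
    dropped = {
        "failed_diff": int((~pass_diff).sum()),
        "failed_p": int((~pass_p).sum()),
        "kept": int(len(kept)),
    }
    return RegionSet(kept, name=name), dropped


def classify_dmr(
    delta_es: float, delta_fib: float, config: ClassificationConfig = ClassificationConfig()
) -> str:
    """Classify one DMR from its two methylation deltas (see module table)."""
    if np.isnan(delta_es) or np.isnan(delta_fib):
        raise ValueError("both deltas must be defined to classify a DMR")
    return str(
        classify_deltas(np.array([delta_es]), np.array([delta_fib]), config)[0]
    )


def classify_deltas(
    delta_es: np.ndarray, delta_fib: np.ndarray, config: ClassificationConfig = ClassificationConfig()
) -> np.ndarray:
    """Vectorized classification; the seven labels tile the delta plane."""
    t = config.threshold
    de = np.asarray(delta_es, dtype=float)
    df_ = np.asarray(delta_fib, dtype=float)
    conds = [
        np.abs(de) <= t,
        (de < -t) & (np.abs(df_) <= t),
        (de < -t) & (df_ > t),
        (de < -t) & (df_ < -t),
        (de > t) & (df_ > t),
        (de > t) & (np.abs(df_) <= t),
        (de > t) & (df_ < -t),
    ]
    labels = [
        "below_threshold",
        "memory",
        "partial_memory",
        "aberrant_hypo",
        "aberrant_hyper",
        "memory_hyper",
        "partial_hyper",
    ]
    out = np.select(conds, labels, default="")
    if (out == "").any():
        raise ValueError("unclassifiable delta pair (NaN input?)")
    return out


def classify_dmr_set(
    levels: pd.DataFrame,
    test_group: str,
    fib_group: str = "fibroblast",
    es_group: str = "hES",
    config: ClassificationConfig = ClassificationConfig(),
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every DMR in a per-group level table.

    ``levels`` is indexed by DMR id with one column per group (mCG/CG).
    Returns the table augmented with ``delta_es, delta_fib, class_label``
    plus the fraction of evaluable DMRs per class.  DMRs with an undefined
    level in any required group are left unlabelled (NaN) and excluded from
    the fractions.
    """
    for g in (test_group, fib_group, es_group):
        if g not in levels.columns:
            raise ValueError(f"group {g!r} missing from level table")
    out = levels.copy()
    out["delta_es"] = out[test_group] - out[es_group]
    out["delta_fib"] = out[test_group] - out[fib_group]
    ok = out["delta_es"].notna() & out["delta_fib"].notna()
    out["class_label"] = pd.NA
    if ok.any():
        out.loc[ok, "class_label"] = classify_deltas(
            out.loc[ok, "delta_es"].to_numpy(), out.loc[ok, "delta_fib"].to_numpy(), config
        )
    counts = out.loc[ok, "class_label"].value_counts()
    fractions = (counts / counts.sum()).reindex(CLASS_LABELS, fill_value=0.0)
    return out, fractions


def assess_correction(
    levels: pd.DataFrame,
    test_group: str,
    reference_group: str = "hES",
    config: ClassificationConfig = ClassificationConfig(),
) -> tuple[pd.Series, float]:
    """Which DMRs did a reprogramming strategy correct to the reference state?

    A DMR is corrected when |level_test - level_reference| is strictly below
    the threshold.  DMRs undefined in either group are excluded from the
    fraction.  Returns the per-DMR boolean series (NA where not evaluable)
    and the corrected fraction over evaluable DMRs.
    """
    for g in (test_group, reference_group):
        if g not in levels.columns:
            raise ValueError(f"group {g!r} missing from level table")
    diff = (levels[test_group] - levels[reference_group]).abs()
    evaluable = diff.notna()
    if not evaluable.any():
        raise ValueError("no DMR has defined levels in both groups")
    corrected = pd.Series(pd.NA, index=levels.index, dtype="boolean")
    corrected[evaluable] = diff[evaluable] < config.threshold
    fraction = float(corrected[evaluable].mean())
    return corrected, fraction


def timecourse_delta(
    dmrs: RegionSet,
    samples: list[tuple[str, MethylomeTable]],
    baseline: str | None = None,
    context: str = "CG",
) -> pd.Series:
    """Mean methylation change at the DMRs for each time point vs baseline.

    ``samples`` is an ordered list of (label, table); the baseline defaults to
    the first label (day 0).  For each sample the mean over DMRs of
    (level_sample - level_baseline) is reported, excluding DMRs undefined in
    either member of the pair.  A sample with no evaluable DMR gets NaN.
    """
    if not samples:
        raise ValueError("no samples provided")
    labels = [lab for lab, _ in samples]
    if baseline is None:
        baseline = labels[0]
    if baseline not in labels:
        raise ValueError(f"baseline {baseline!r} not among sample labels")
    per_sample = {
        lab: weighted_methylation(tab, dmrs, context=context) for lab, tab in samples
    }
    base = per_sample[baseline]
    out = {}
    for lab in labels:
        diff = per_sample[lab] - base
        out[lab] = float(diff.mean()) if diff.notna().any() else np.nan
    return pd.Series(out, name="mean_delta")


def icr_screen(
    table: MethylomeTable,
    icrs: RegionSet,
    margin: float = 0.15,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Screen imprint control regions for loss of the balanced ~50% state.

    Germline ICRs carry one methylated and one unmethylated parental allele,
    so the expected mCG/CG is ~0.5.  Each ICR whose level deviates from 0.5
    by more than ``margin`` is flagged.  Returns the per-ICR table and a
    summary (median, IQR bounds, flagged count) over ICRs with defined levels.
    """
    levels = weighted_methylation(table, icrs, context="CG")
    out = pd.DataFrame({"level": levels})
    flagged = pd.array((levels - 0.5).abs() > margin, dtype="boolean")
    flagged[levels.isna().to_numpy()] = pd.NA
    out["flagged"] = flagged
    defined = levels.dropna()
    summary = {
        "n": int(levels.size),
        "n_defined": int(defined.size),
        "median": float(defined.median()) if len(defined) else float("nan"),
        "q1": float(defined.quantile(0.25)) if len(defined) else float("nan"),
        "q3": float(defined.quantile(0.75)) if len(defined) else float("nan"),
        "n_flagged": int(out["flagged"].dropna().astype(bool).sum()),
    }
    return out, summary
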
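# Methods

This note documents the models implemented in `epimemory`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Coordinates and methylation levels

Per-cytosine positions are 1-based (CGmap convention); intervals are 0-based
half-open (BED convention); a cytosine at position `pos` belongs to
`[start, end)` iff `start < pos <= end`. Conversions happen only at I/O
boundaries.

The methylation level of a region is the coverage-weighted mean
`sum(mC) / sum(mC + C)` over in-region cytosines of the requested context.
Weighting by coverage (rather than averaging per-site levels) is the
standard WGBS estimator: it is the maximum-likelihood level under binomial
sampling and keeps low-coverage sites from dominating.

Conventions chosen where the procedure admits variants:

* **Undefined vs zero.** A region with no covered site of the context
  returns NaN, never 0, so downstream deltas cannot fabricate signal from
  missing coverage.
* **Non-conversion floor.** For non-CG contexts the context-specific
  non-conversion rate (the apparent methylation of an unmethylated spike-in
  genome, typically < 1 %) is subtracted; at low depth the difference can go
  negative and is floored at 0. CG levels are never corrected — the
  correction is negligible against mCG ~ 0.8 but decisive for mCA ~ 0.01–0.05.
* **Strand collapsing.** Symmetric CpG calls (plus strand at p, minus at
  p+1) are summed into one record at p; unpaired calls are kept. Total mC
  and coverage are conserved.
* **Sliding windows** (default 5 kb window, 1 kb step for mCA tracks) tile
  each contig from 0 and are emitted only when fully contained in the contig
  and covering at least one informative site; partial terminal windows are
  dropped.
* **Per-read classes.** A read is `methylated` when every covered CG is
  called methylated, `unmethylated` when none is, `partial` otherwise. A
  single-call read can therefore only be methylated or unmethylated. Reads
  are attributed to a region if they contribute at least one CG call to it.

## DMR classification and correction

DMRs arrive pre-detected (interval + methylation difference + p-value) and
are filtered with strict inequalities: |difference| > 0.2 and p < 0.05.
Classification uses two deltas per DMR, Δes = hiPS − hES and Δfib = hiPS −
fibroblast, with threshold t = 0.2 mCG/CG:

| condition | label |
|---|---|
| \|Δes\| ≤ t | below_threshold |
| Δes < −t, \|Δfib\| ≤ t | memory |
| Δes < −t, Δfib > t | partial_memory |
| Δes < −t, Δfib < −t | aberrant_hypo |
| Δes > t, Δfib > t | aberrant_hyper |
| Δes > t, \|Δfib\| ≤ t | memory_hyper |
| Δes > t, Δfib < −t | partial_hyper |

Equality with the threshold is assigned to the no-difference side, and
correction (|test − reference| < t) is strict, so boundary values are
reproducible. The seven predicates tile the delta plane — every defined pair
gets exactly one label (property-tested over 10^5 random pairs). The
`aberrant_hypo` and `partial_hyper` corners are rare in practice but named
for completeness; `below_threshold` preserves DMRs whose re-quantified Δes
no longer clears the threshold rather than silently dropping them.

ICRs are screened by their mCG level against the balanced two-allele
expectation of 0.5; the flagging margin defaults to |level − 0.5| > 0.15 and
is configurable — it is a screening aid, not a statistical test.

## Domain profiles

Each domain's body and equal-length upstream/downstream flanks are split
into 30 bins (90 bins total). When the length is not divisible by 30 the
remainder r is absorbed one extra bp by the first r bins — deterministic and
exactly partitioning. Per-region profiles are normalized by the maximum over
all 90 bins of that region (so flanks plateau near 1 and the normalization
is idempotent); per-bin means across regions exclude NaN bins pairwise.
Flank length equals body length; domains whose flanks fall off the contig
are skipped with a warning. Domains are treated strand-agnostically.

## Permutation enrichment

The statistic is the count of query regions overlapping a feature track by
at least 1 bp (each query counted once — not bp of overlap). The null
re-places every query interval uniformly at random on its own chromosome,
width preserved, optionally outside a mask; keeping the chromosome respects
large-scale composition structure. z = (observed − perm mean)/perm sd;
empirical p uses the add-one estimator (never 0); FDR across tracks is
Benjamini–Hochberg; permutations are shared across tracks. With perm sd = 0
the result is flagged degenerate instead of dividing by zero. This scheme is
calibrated by construction: against uniformly placed features the z is
approximately standard normal (measured in the acceptance run). GC- or
gap-matched backgrounds and circular-shift nulls are out of scope.

## Trajectory clustering

Elements with less than 0.2 mCG range across the time course, or any
undefined value, are removed before clustering. Rows are standardized (mean
0, sd 1) so clusters group by trajectory shape, then clustered with Bezdek
fuzzy c-means (fuzzifier m = 2 by default; update rules in the module
docstring). Centers initialize at k distinct element rows (seeded) and the
alternating updates stop when the largest center movement is below 1e−6;
the objective is non-increasing across iterations and memberships row-sum to
1 (both asserted in tests). A point coincident with a center takes
membership 1 there (split equally among coincident centers). k is the
caller's choice; a silhouette-over-k helper is provided. Cluster
correspondence between two time courses is by greedy descending-Jaccard
matching of membership cores (membership ≥ 0.5, Jaccard ≥ 0.5, each cluster
used once) — the cut-offs are exposed as parameters since any core/overlap
definition is a modelling choice.

Expression summaries weight each linked gene's (quantile-normalized) TPM by
its element–gene interaction score, down-weighting weakly linked genes, and
report the nonparametric bootstrap mean with a percentile confidence band
(default 99 %) over resampled links. A single-link cluster yields a
zero-width band; a cluster with no linked genes is skipped with a warning.

## Insertion sites and clonal diversity

Alignment pairs are kept when the read has both a genome and a vector hit,
the genome hit is primary, ≥ 800 bp and at MAPQ exactly 60 (a `>=` mode is
available behind a flag), and the read-coordinate gap between the two hits
is ≤ 50 bp (overlapping hits count as gap 0). Each rejected read is tallied
under the first criterion it violates, so tallies partition the input.

The junction is the genome-hit boundary adjacent to the vector on the read:
with the vector 3' of the genome alignment, the genome alignment's read-end
maps to `g_end` on the plus strand and `g_start` on the minus strand, and
symmetrically for a 5' vector. Junctions are clustered by transitive single
linkage within 50 bp (matching interval-cluster tools, not fixed-window
binning); the cluster interval spans the smallest to the largest member
junction and its coverage is the member count.

With n observed sites and R total supporting reads, the total diversity
N̂ solves `N (1 − exp(−R/N)) = n` by fixed-point iteration from N₀ = n —
the zero-truncated Poisson abundance estimate (per-site counts Poisson(R/N),
observed sites are those with count > 0). When R = n (every site a
singleton) no finite root exists and the estimate is flagged unconverged and
unbounded. The uncertainty interval is a Poisson bootstrap: each read gets
an independent Poisson(1) weight — equivalently each site's coverage is
resampled as Poisson(coverage) — and the estimator is re-run on the
surviving sites. A replicate is a second truncation of already-truncated
data, so replicate estimates center systematically below N̂; the raw
percentile interval therefore has essentially zero coverage of the truth.
The reported interval is the **recentred percentile interval** (the
replicate distribution shifted so its mean equals N̂), which preserves the
bootstrap's spread — the quantity it estimates well — and discards its
mechanical bias; under the simulated study condition (1000 true sites, 3
reads per site) its measured coverage is near nominal (computed by the
acceptance run and tests). Replicates that degenerate (all singletons) are
dropped from the interval and counted.

## Synthetic data: what it emulates and what it does not

The generator produces every input type with planted truth: per-group
methylomes with planted DMRs/PMDs/CH-DMRs/balanced ICRs and a fully
unmethylated spike-in contig; per-read epiallele libraries; feature tracks
with controlled overlap enrichment; Cas9-enrichment alignment-pair tables;
and trajectory matrices with planted clusters.

Deliberate simplifications:

* Cytosine sites sit on a fixed 100-bp grid per contig (one symmetric CpG
  pair, two CA sites and one CT site per tile). Site density and sequence
  context are irrelevant to the estimators tested, and a deterministic map
  simplifies truth bookkeeping; it does not reproduce CpG islands or
  density-dependent coverage biases.
* Coverage is Poisson around the mean depth, floored at 1 inside planted
  regions (so no planted region is silently unobserved) and on the spike-in;
  zero-coverage sites elsewhere are dropped. Observed methylated counts are
  binomial at `true + (1 − true) · nonconversion` — non-conversion acts on
  the unmethylated fraction only. There is no strand bias, no mapping error
  and no within-region heterogeneity beyond the binomial noise.
* Feature tracks place each feature independently: with probability
  `fold × p0` uniformly within the query-overlapping start space, otherwise
  uniformly outside it, where p0 is the overlap probability of a uniformly
  placed feature. fold = 1 is therefore *exactly* uniform placement — a
  clean null for calibration; `fold × p0 > 1` is rejected.
* Insertion libraries place true sites on a 1-kb grid (≥ 1 kb apart, so
  planted sites never merge during clustering), draw per-site read counts
  Poisson(λ), and jitter junctions ±10 bp. Noise reads violate exactly one
  filter criterion each, making rejection tallies exactly auditable.
* Trajectory backgrounds are flat (range < 0.2 by construction), so the
  dynamic-element filter separates them perfectly at zero noise.

Consequently, passing tests demonstrate estimator correctness and
calibration under the stated sampling models — not robustness to alignment
artefacts, copy-number variation, bisulfite degradation or cell-population
heterogeneity, none of which are simulated.

## Problem sizes used in tests and the acceptance run

Synthetic studies run at the conditions the estimators target: 30×
coverage, 300 planted DMRs with effect sizes ≥ 0.3 across 20 seeds for
class recovery; 50× over > 10^4 spike-in sites for non-conversion; 10^4
reads for epiallele calibration; 20 seeds of a 60-kb CH-DMR for profiles;
100 seeds × 200 permutations for enrichment calibration; 1000 true sites at
λ = 3 with 200 bootstrap replicates × 100 libraries for diversity coverage;
500 replicates × 1000 bootstrap draws for expression-band coverage. These
sizes give stable pass/fail behaviour at seeded reproducibility.

## Known limitations

* DMR and CH-DMR *detection* are out of scope: intervals are consumed, not
  discovered, so results inherit any bias of the upstream detector.
* The diversity model assumes one shared Poisson rate per library;
  clone-size heterogeneity (over-dispersion) biases N̂ downward, and the
  bootstrap does not correct for it.
* The enrichment null preserves chromosome and width only; enrichment
  against features that track GC or assembly gaps will reflect those
  covariates.
* Quantile normalization uses the standard per-rank column mean with tie
  averaging; it assumes comparable distributions across samples.
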
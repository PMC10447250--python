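"""Fuzzy c-means clustering of methylation trajectories across reprogramming.

Regulatory elements whose mCG/CG changes by at least 20 percentage points at
any time through a reprogramming time course are clustered with standard
(Bezdek) fuzzy c-means after per-element standardization, mirroring the
soft-clustering workflow commonly applied to expression/methylation time
series.  Updates with fuzzifier m > 1:

    u_ij = 1 / sum_l (d_ij / d_lj)^(2/(m-1))
    c_i  = sum_j u_ij^m x_j / sum_j u_ij^m

The objective J = sum_ij u_ij^m d_ij^2 is non-increasing across iterations.
Clusters found separately in two time courses (e.g. primed and naive
reprogramming) can be merged when their high-membership cores overlap, and
the expression of genes linked to each cluster's elements is summarized as a
nonparametric bootstrap mean with a percentile confidence band, with each
gene's TPM weighted by the element-gene interaction score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FuzzyClustering",
    "filter_dynamic_elements",
    "fuzzy_cmeans",
    "merge_overlapping_clusters",
    "quantile_normalize",
    "weighted_expression_summary",
    "silhouette_over_k",
]


@dataclass
class FuzzyClustering:
    k: int
    m: float
    centers: np.ndarray  # (k, T) in standardized units
    centers_raw: np.ndarray  # (k, T) in original (mCG/CG) units
    memberships: pd.DataFrame  # element x k, rows sum to 1
    objective: float
    objective_history: np.ndarray
    converged: bool
    n_iter: int
    timepoints: list[str] = field(default_factory=list)

    def hard_assignment(self) -> pd.Series:
        """Cluster index of maximal membership per element."""
        return pd.Series(
            np.argmax(self.memberships.to_numpy(), axis=1),
            index=self.memberships.index,
            name="cluster",
        )

    def cores(self, core_membership: float = 0.5) -> list[set[str]]:
        """Per cluster, the elements with membership >= the core cut-off."""
        u = self.memberships
        return [set(u.index[u.iloc[:, i] >= core_membership]) for i in range(self.k)]


def filter_dynamic_elements(matrix: pd.DataFrame, min_change: float = 0.2) -> pd.DataFrame:
    """Keep elements whose methylation range (max - min over time) >= min_change.

    Elements with any undefined value are dropped first (their range is not
    evaluable).  Raises when nothing survives.
    """
    complete = matrix.dropna()
    rng = complete.max(axis=1) - complete.min(axis=1)
    kept = complete[rng >= min_change]
    if kept.empty:
        raise ValueError("no element passes the dynamic-methylation filter")
    return kept


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant trajectories cannot be standardized; filter first")
    return (x - mu) / sd


def _memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """FCM membership update; a point coincident with a center gets membership 1."""
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)  # (n, k)
    u = np.empty_like(d2)
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = d2[~any_zero][:, :, None] / d2[~any_zero][:, None, :]  # d_ij / d_lj
        u[~any_zero] = 1.0 / (ratio ** (1.0 / (m - 1.0))).sum(axis=2)
    if any_zero.any():
        u[any_zero] = 0.0
        rows = np.flatnonzero(any_zero)
        for r in rows:
            cols = np.flatnonzero(zero[r])
            u[r, cols] = 1.0 / len(cols)
    return u


def fuzzy_cmeans(
    matrix: pd.DataFrame,
    k: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> FuzzyClustering:
    """Bezdek fuzzy c-means on row-standardized trajectories.

    Rows are standardized to mean 0, sd 1 (so clusters group by trajectory
    *shape*, not absolute level); centers are initialized as k distinct
    element rows chosen at random (seeded), or at ``init`` (a (k, T) array in
    standardized units) when given.  Iterates membership/center
    updates until the largest center movement is below ``tol`` or ``max_iter``
    is hit (then ``converged`` is False).  Centers are reported in both
    standardized and original mCG/CG units (the latter as the u^m-weighted
    mean of the original rows).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(matrix) <= k:
        raise ValueError(f"need more than k={k} elements, got {len(matrix)}")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    raw = matrix.to_numpy(dtype=float)
    x = _standardize_rows(raw)
    if init is not None:
        centers = np.asarray(init, dtype=float).copy()
        if centers.shape != (k, x.shape[1]):
            raise ValueError("init must have shape (k, n_timepoints)")
    else:
        rng = np.random.default_rng(seed)
        centers = x[rng.choice(len(x), size=k, replace=False)].copy()
    history = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        u = _memberships(x, centers, m)
        um = u ** m
        new_centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - new_centers[None, :, :]) ** 2).sum(axis=2)
        history.append(float((um * d2).sum()))
        move = np.abs(new_centers - centers).max()
        centers = new_centers
        if move < tol:
            converged = True
            break
    u = _memberships(x, centers, m)
    um = u ** m
    centers_raw = (um.T @ raw) / um.sum(axis=0)[:, None]
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    objective = float((um * d2).sum())
    return FuzzyClustering(
        k=k,
        m=m,
        centers=centers,
        centers_raw=centers_raw,
        memberships=pd.DataFrame(u, index=matrix.index, columns=range(k)),
        objective=objective,
        objective_history=np.asarray(history),
        converged=converged,
        n_iter=n_iter,
        timepoints=list(matrix.columns),
    )


def merge_overlapping_clusters(
    a: FuzzyClustering,
    b: FuzzyClustering,
    core_membership: float = 0.5,
    jaccard_min: float = 0.5,
) -> list[tuple[int, int, float]]:
    """Match clusters between two time courses by core overlap.

    Cluster cores are the elements with membership >= ``core_membership``;
    cluster pairs with Jaccard index >= ``jaccard_min`` between their cores
    are merged greedily in descending Jaccard order, each cluster used at
    most once.  Returns (cluster_in_a, cluster_in_b, jaccard) tuples.
    """
    cores_a = a.cores(core_membership)
    cores_b = b.cores(core_membership)
    pairs = []
    for i, ca in enumerate(cores_a):
        for j, cb in enumerate(cores_b):
            union = ca | cb
            if not union:
                continue
            jac = len(ca & cb) / len(union)
            if jac >= jaccard_min:
                pairs.append((i, j, jac))
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    merges = []
    for i, j, jac in pairs:
        if i in used_a or j in used_b:
            continue
        merges.append((i, j, jac))
        used_a.add(i)
        used_b.add(j)
    return merges


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns: after normalization every column has the
    same sorted values (the per-rank mean across columns).  Ties within a
    column receive the mean of their rank values."""
    x = matrix.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="mergesort")
    ranked = np.take_along_axis(x, order, axis=0)
    rank_means = ranked.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        # average rank-mean over tied values
        col = x[:, j]
        sorted_idx = order[:, j]
        vals = rank_means.copy()
        # group ties
        srt = col[sorted_idx]
        start = 0
        for i in range(1, len(srt) + 1):
            if i == len(srt) or srt[i] != srt[start]:
                vals[start:i] = vals[start:i].mean()
                start = i
        out[sorted_idx, j] = vals
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def weighted_expression_summary(
    tpm: pd.DataFrame,
    links: pd.DataFrame,
    clusters: pd.Series,
    n_boot: int = 1000,
    ci: float = 0.99,
    seed: int = 0,
) -> dict[int, pd.DataFrame]:
    """Bootstrap summary of interaction-score-weighted expression per cluster.

    ``tpm`` is gene x timepoint (quantile-normalize upstream with
    :func:`quantile_normalize`); ``links`` has columns
    ``element, gene, score``; ``clusters`` maps element id -> cluster id.
    Each link contributes TPM x score (down-weighting weakly linked genes);
    the bootstrap resamples links and reports the mean and the percentile
    confidence interval per timepoint.  Clusters with no linked gene in the
    matrix are skipped with a warning entry (empty frame).
    """
    for col in ("element", "gene", "score"):
        if col not in links.columns:
            raise ValueError(f"links table lacks column {col!r}")
    if not 0 < ci < 1:
        raise ValueError("ci must be in (0,1)")
    rng = np.random.default_rng(seed)
    alpha = (1 - ci) / 2
    out: dict[int, pd.DataFrame] = {}
    for cid in sorted(clusters.unique()):
        members = set(clusters.index[clusters == cid])
        sub = links[links["element"].isin(members) & links["gene"].isin(tpm.index)]
        if sub.empty:
            warnings.warn(f"cluster {cid} has no linked gene in the expression matrix")
            out[int(cid)] = pd.DataFrame(columns=["mean", "lo", "hi"])
            continue
        w = tpm.loc[sub["gene"]].to_numpy() * sub["score"].to_numpy()[:, None]
        n = len(w)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = w[idx].mean(axis=1)  # (n_boot, T)
        out[int(cid)] = pd.DataFrame(
            {
                "mean": w.mean(axis=0),
                "lo": np.quantile(boot_means, alpha, axis=0),
                "hi": np.quantile(boot_means, 1 - alpha, axis=0),
                "n_links": n,
            },
            index=tpm.columns,
        )
    return out


def silhouette_over_k(
    matrix: pd.DataFrame,
    k_values: list[int],
    m: float = 2.0,
    seed: int = 0,
) -> pd.Series:
    """Helper report: silhouette score of the hard FCM assignment per k.

    Provided to inform the caller's choice of k; picking k remains the
    caller's decision.
    """
    from sklearn.metrics import silhouette_score

    x = _standardize_rows(matrix.to_numpy(dtype=float))
    scores = {}
    for k in k_values:
        fc = fuzzy_cmeans(matrix, k=k, m=m, seed=seed)
        scores[k] = float(silhouette_score(x, fc.hard_assignment().to_numpy()))
    return pd.Series(scores, name="silhouette")
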
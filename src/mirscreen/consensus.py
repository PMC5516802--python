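"""Resampled k-means consensus clustering of miRNAs and marker discovery.

miRNAs are grouped by the frequency with which they co-cluster across
resampled k-means runs (100 repetitions, each leaving out 10% of the
miRNAs).  The number of clusters is chosen by the delta-area rule on the
empirical CDF of consensus values, and final labels come from
average-linkage hierarchical clustering of the consensus matrix.
Cluster-defining proteins are ranked by one-vs-rest random-forest
permutation importance measured on out-of-bag samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.tree import DecisionTreeClassifier

from .screens import ScreenMatrix

__all__ = [
    "ConsensusResult",
    "MarkerReport",
    "consensus_cluster",
    "consensus_matrix_from_runs",
    "select_k",
    "rank_markers",
]


@dataclass
class ConsensusResult:
    """Per-k consensus matrices and the model-selection summary."""

    k_range: list[int]
    consensus: dict[int, np.ndarray]        # M(k), NaN where never co-sampled
    cosample_counts: dict[int, np.ndarray]  # times each pair was co-sampled
    area: dict[int, float] = field(default_factory=dict)       # A(k)
    delta_area: dict[int, float] = field(default_factory=dict)  # Delta(k)
    pac: dict[int, float] = field(default_factory=dict)        # ambiguity per k
    selected_k: int | None = None
    labels: np.ndarray | None = None
    n_resamples: int = 0
    holdout_frac: float = 0.0
    undefined_pairs: dict[int, int] = field(default_factory=dict)
    single_k_warning: bool = False


@dataclass
class MarkerReport:
    """Per-cluster protein rankings by permutation importance (non-increasing)."""

    rankings: dict[int, list[tuple[str, float]]]
    n_trees: int
    n_permutations: int
    skipped_clusters: list[int] = field(default_factory=list)


def consensus_matrix_from_runs(
    runs: list[tuple[np.ndarray, np.ndarray]], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Consensus matrix from explicit (sampled indices, labels) runs.

    ``M[i, j]`` = co-cluster count / co-sample count over the runs in
    which both items were sampled; NaN where a pair was never co-sampled.
    This is the accumulation core of :func:`consensus_cluster`, exposed so
    small cases can be checked by hand.
    """
    co = np.zeros((n, n))
    cos = np.zeros((n, n))
    for idx, labels in runs:
        idx = np.asarray(idx)
        labels = np.asarray(labels)
        same = (labels[:, None] == labels[None, :]).astype(float)
        co[np.ix_(idx, idx)] += same
        cos[np.ix_(idx, idx)] += 1.0
    with np.errstate(invalid="ignore"):
        m = np.where(cos > 0, co / np.where(cos > 0, cos, 1.0), np.nan)
    return m, cos


def _cdf_area(m: np.ndarray) -> float:
    """Area under the empirical CDF of upper-triangle consensus values."""
    vals = m[np.triu_indices(m.shape[0], k=1)]
    vals = np.sort(vals[~np.isnan(vals)])
    if vals.size == 0:
        return 0.0
    n = vals.size
    return float(np.sum(np.diff(vals) * (np.arange(1, n) / n)))


def _pac(m: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> float:
    """Proportion of ambiguous clustering: consensus values in (lo, hi)."""
    vals = m[np.triu_indices(m.shape[0], k=1)]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return 1.0
    return float(((vals > lo) & (vals < hi)).mean())


def select_k(result: ConsensusResult, delta_min: float = 0.025,
             pac_max: float = 0.05) -> int:
    """Pick the number of clusters from the consensus-value distribution.

    A candidate k must gain CDF area (``Delta(k_min) = A(k_min)``,
    ``Delta(k) = (A(k) - A(k-1)) / A(k-1)`` for larger k, required
    >= ``delta_min``) *and* cluster unambiguously (proportion of
    consensus values in (0.1, 0.9) at most ``pac_max``).  The largest
    qualifying k wins; ties break toward smaller k, and when no k
    qualifies the smallest k in the range is returned.  The ambiguity
    guard is needed because a large unstructured group keeps gaining
    area when it is split stably, while its consensus values betray the
    split's arbitrariness.  A singleton k_range returns that k with
    ``single_k_warning`` set.
    """
    ks = sorted(result.k_range)
    for k in ks:
        if k not in result.area:
            result.area[k] = _cdf_area(result.consensus[k])
        if k not in result.pac:
            result.pac[k] = _pac(result.consensus[k])
    if len(ks) == 1:
        result.single_k_warning = True
        result.delta_area[ks[0]] = result.area[ks[0]]
        result.selected_k = ks[0]
        return ks[0]
    selected = ks[0]
    for i, k in enumerate(ks):
        if i == 0:
            d = result.area[k]
        else:
            prev = result.area[ks[i - 1]]
            d = (result.area[k] - prev) / prev if prev > 0 else 0.0
        result.delta_area[k] = d
        if d >= delta_min and result.pac[k] <= pac_max:
            selected = k
    result.selected_k = selected
    return selected


def consensus_cluster(
    screen: ScreenMatrix,
    k_range: range | list[int] = range(2, 16),
    n_resamples: int = 100,
    holdout_frac: float = 0.10,
    n_init: int = 10,
    delta_min: float = 0.025,
    pac_max: float = 0.05,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus k-means over a k range with per-resample holdout.

    For each k, ``n_resamples`` k-means runs (Lloyd's algorithm,
    k-means++ seeding, ``n_init`` restarts, max 300 iterations) are fitted
    on a random 1 - holdout_frac subset of miRNAs; pairwise co-clustering
    frequencies form M(k).  The number of clusters is then selected by
    the delta-area rule and final labels are obtained by average-linkage
    hierarchical clustering of 1 - M(selected_k).

    Randomness derives from one master seed via per-(k, resample) counter
    substreams, so runs are reproducible and order-independent.
    """
    x = screen.values
    n = x.shape[0]
    ks = sorted(int(k) for k in k_range)
    n_keep = n - int(round(holdout_frac * n))
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if ks[-1] > n_keep:
        raise ValueError(
            f"holdout_frac={holdout_frac} leaves {n_keep} rows, fewer than "
            f"k={ks[-1]} clusters"
        )
    consensus: dict[int, np.ndarray] = {}
    cosample: dict[int, np.ndarray] = {}
    undefined: dict[int, int] = {}
    for k in ks:
        runs = []
        for r in range(n_resamples):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k, r)))
            idx = rng.choice(n, size=n_keep, replace=False)
            idx.sort()
            km = KMeans(
                n_clusters=k, init="k-means++", n_init=n_init, max_iter=300,
                tol=1e-6, algorithm="lloyd",
                random_state=int(rng.integers(2**31 - 1)),
            )
            labels = km.fit_predict(x[idx])
            runs.append((idx, labels))
        m, cos = consensus_matrix_from_runs(runs, n)
        consensus[k] = m
        cosample[k] = cos
        off = cos[np.triu_indices(n, k=1)]
        undefined[k] = int((off == 0).sum())
    result = ConsensusResult(
        k_range=ks, consensus=consensus, cosample_counts=cosample,
        n_resamples=n_resamples, holdout_frac=holdout_frac,
        undefined_pairs=undefined,
    )
    k_sel = select_k(result, delta_min=delta_min, pac_max=pac_max)
    m = consensus[k_sel].copy()
    nan = np.isnan(m)
    if nan.any():
        m[nan] = np.nanmean(m)
    np.fill_diagonal(m, 1.0)
    dist = 1.0 - (m + m.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    result.labels = cut_tree(z, n_clusters=k_sel).ravel() + 1
    return result


def rank_markers(
    screen: ScreenMatrix,
    labels: np.ndarray,
    n_trees: int = 500,
    n_permutations: int = 10,
    min_cluster_size: int = 5,
    seed: int = 0,
) -> MarkerReport:
    """Rank cluster-discriminating proteins by out-of-bag permutation importance.

    For each cluster a one-vs-rest ensemble of bootstrapped randomized
    decision trees (``max_features=sqrt(p)``) is fitted.  A protein's
    importance is the mean decrease in out-of-bag accuracy when its
    column is permuted (averaged over trees and ``n_permutations``
    repeats; trees that never split on the protein contribute zero).
    Negative means are clipped to zero.  Clusters smaller than
    ``min_cluster_size`` are skipped with a warning.
    """
    labels = np.asarray(labels)
    x = screen.values
    n, p = x.shape
    cluster_ids = sorted(set(labels.tolist()))
    if len(cluster_ids) < 2:
        raise ValueError("need at least 2 clusters to rank markers")
    rankings: dict[int, list[tuple[str, float]]] = {}
    skipped: list[int] = []
    master = np.random.SeedSequence(seed, spawn_key=(40,))
    for ci, cid in enumerate(cluster_ids):
        y = (labels == cid).astype(int)
        if y.sum() < min_cluster_size:
            warnings.warn(
                f"cluster {cid} has {y.sum()} members < {min_cluster_size}; skipped"
            )
            skipped.append(cid)
            continue
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(40, ci)))
        drop = np.zeros(p)
        n_used = np.zeros(p)
        for t in range(n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
            if oob.size == 0 or len(np.unique(y[boot])) < 2:
                continue
            tree = DecisionTreeClassifier(
                max_features="sqrt", random_state=int(rng.integers(2**31 - 1))
            )
            tree.fit(x[boot], y[boot])
            base = (tree.predict(x[oob]) == y[oob]).mean()
            used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
            for f in used:
                dec = 0.0
                xo = x[oob].copy()
                for _ in range(n_permutations):
                    xo[:, f] = rng.permutation(x[oob, f])
                    dec += base - (tree.predict(xo) == y[oob]).mean()
                drop[f] += dec / n_permutations
                n_used[f] += 1
        imp = np.where(n_used > 0, drop / n_trees, 0.0)
        imp = np.clip(imp, 0.0, None)
        order = np.argsort(-imp, kind="stable")
        rankings[cid] = [(screen.protein_ids[j], float(imp[j])) for j in order]
    return MarkerReport(rankings, n_trees=n_trees, n_permutations=n_permutations,
                        skipped_clusters=skipped)
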
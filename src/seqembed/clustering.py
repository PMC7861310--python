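"""Clustering of embedded state rows and partition-agreement scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "ClusteringResult",
    "kmeans_pp",
    "agglomerative_cosine_single",
    "ari",
    "matched_accuracy",
    "majority_vote",
]


@dataclass
class ClusteringResult:
    labels: np.ndarray
    k: int
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)


def kmeans_pp(
    points: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10,
) -> ClusteringResult:
    """K-means with D^2-weighted seeding; best of ``n_restarts`` by
    within-cluster sum of squares. Deterministic for a fixed seed."""
    points = np.asarray(points, dtype=float)
    P = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > P:
        raise ValueError(f"k={k} exceeds number of points P={P}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_restarts,
        max_iter=300, tol=1e-6, random_state=seed,
    ).fit(points)
    return ClusteringResult(labels=km.labels_, k=k, method="kmeans++", seed=seed)


def agglomerative_cosine_single(points: np.ndarray, k: int) -> ClusteringResult:
    """Bottom-up merging under single linkage with cosine distance
    (1 - cosine similarity) until k clusters remain."""
    points = np.asarray(points, dtype=float)
    P = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > P:
        raise ValueError(f"k={k} exceeds number of points P={P}")
    norms = np.linalg.norm(points, axis=1)
    bad = np.flatnonzero(norms == 0.0)
    if bad.size:
        raise ValueError(f"cosine distance undefined for zero-norm row {bad[0]}")
    if k == P:
        labels = np.arange(P)
    else:
        Z = linkage(points, method="single", metric="cosine")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return ClusteringResult(labels=labels, k=k, method="agglomerative-cosine-single")


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions, from the contingency
    table. Permutation-invariant; 1 iff the partitions are identical."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    table = _contingency(a, b)
    n = a.size

    def comb2(x):
        return x * (x - 1) / 2.0

    index = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions trivial (all-singletons vs all-singletons, or
        # single cluster vs single cluster): identical by construction
        return 1.0
    return float((index - expected) / (max_index - expected))


def matched_accuracy(pred_labels, true_labels) -> float:
    """Fraction of agreeing positions under the best one-to-one matching
    of predicted clusters to reference classes (Hungarian on the
    confusion matrix)."""
    pred = np.asarray(pred_labels).ravel()
    true = np.asarray(true_labels).ravel()
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.size} vs {true.size}")
    if pred.size == 0:
        raise ValueError("empty labelings")
    table = _contingency(pred, true)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum() / pred.size)


def majority_vote(labels: np.ndarray, groups: np.ndarray) -> dict[int, int]:
    """Per-group majority label; ties resolved toward the lower label id."""
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(groups, dtype=int)
    if labels.shape != groups.shape:
        raise ValueError("labels and groups must align")
    out: dict[int, int] = {}
    for g in np.unique(groups):
        votes = np.bincount(labels[groups == g])
        out[int(g)] = int(votes.argmax())  # argmax takes the lowest on ties
    return out
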
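"""Chemotype clustering of similarity-matrix rows and k_VR values.

Two clusterers mirror each other as a robustness check: single-linkage
agglomerative clustering on Euclidean distances, and k-means with
k-means++ restarts.  Cluster number is chosen either by maximizing the
Krzanowski-Lai index

    DIFF_k = (k-1)^(2/p) W_{k-1} - k^(2/p) W_k,   KL(k) = |DIFF_k / DIFF_{k+1}|

(p = feature dimension, W_k = total within-cluster sum of squares), or by
the elbow rule (largest second difference of W_k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .errors import DataError

__all__ = [
    "ClusterAssignment",
    "ClusterScan",
    "single_linkage_cluster",
    "kmeans_cluster",
    "kmeans_wss",
    "kl_select_k",
    "elbow_select_k",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """label -> cluster id (contiguous from 1, ordered by first appearance)."""

    assignment: dict[str, int]
    method: str
    k: int
    seed: int | None = None
    restarts: int | None = None
    linkage_method: str | None = None
    inertia: float | None = None

    def ids_for(self, labels) -> np.ndarray:
        return np.asarray([self.assignment[l] for l in labels])


@dataclass(frozen=True)
class ClusterScan:
    k_values: np.ndarray
    wss: np.ndarray
    diff: dict[int, float]
    kl: dict[int, float]
    chosen_k: int
    rule: str
    low_confidence: bool = False
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _as_features(features, labels):
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise DataError("feature vectors must be finite")
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise DataError("labels and feature rows disagree in length")
    return X, labels


def _canonical_ids(raw_ids: np.ndarray, labels) -> dict[str, int]:
    """Renumber clusters 1..k in order of first appearance over label order."""
    mapping: dict[int, int] = {}
    out = {}
    for lbl, rid in zip(labels, raw_ids):
        if rid not in mapping:
            mapping[rid] = len(mapping) + 1
        out[lbl] = mapping[rid]
    return out


def single_linkage_cluster(
    features, k: int | None = None, height: float | None = None, labels=None
) -> tuple[ClusterAssignment, np.ndarray]:
    """Agglomerative clustering by minimum Euclidean inter-cluster distance.

    Cut the dendrogram to ``k`` clusters or at merge ``height``.  Returns
    the assignment and the scipy linkage matrix (dendrogram).
    """
    X, labels = _as_features(features, labels)
    n = X.shape[0]
    if n < 2:
        raise DataError("need >= 2 items to cluster")
    if (k is None) == (height is None):
        raise DataError("specify exactly one of k or height")
    if k is not None and k > n:
        raise DataError(f"k = {k} exceeds n = {n}")
    with warnings.catch_warnings():
        # SSM rows are deliberately used as feature vectors, which scipy
        # flags as "looks like a distance matrix"
        warnings.filterwarnings("ignore", message=".*uncondensed distance matrix.*")
        Z = linkage(X, method="single", metric="euclidean")
    if k is not None:
        raw = fcluster(Z, t=k, criterion="maxclust")
        kk = k
    else:
        raw = fcluster(Z, t=height, criterion="distance")
        kk = len(set(raw))
    assign = _canonical_ids(raw, labels)
    return (
        ClusterAssignment(assign, method="single-linkage-ahc", k=kk, linkage_method="single"),
        Z,
    )


def kmeans_cluster(
    features, k: int, restarts: int = 50, seed: int = 0, labels=None
) -> ClusterAssignment:
    """k-means (Lloyd, k-means++ init, best of ``restarts`` by W_k)."""
    X, labels = _as_features(features, labels)
    if k > X.shape[0]:
        raise DataError(f"k = {k} exceeds n = {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=restarts, init="k-means++", random_state=seed)
    raw = km.fit_predict(X)
    assign = _canonical_ids(raw, labels)
    return ClusterAssignment(
        assign, method="kmeans", k=k, seed=seed, restarts=restarts,
        inertia=float(km.inertia_),
    )


def kmeans_wss(features, kmax: int, restarts: int = 50, seed: int = 0) -> np.ndarray:
    """W_k (total within-cluster sum of squares) for k = 1..kmax."""
    X, _ = _as_features(features, None)
    wss = []
    for k in range(1, kmax + 1):
        if k == 1:
            centroid = X.mean(axis=0)
            wss.append(float(np.sum((X - centroid) ** 2)))
        else:
            km = KMeans(n_clusters=k, n_init=restarts, init="k-means++", random_state=seed)
            km.fit(X)
            wss.append(float(km.inertia_))
    return np.asarray(wss)


def kl_select_k(
    features, kmax: int, restarts: int = 50, seed: int = 0
) -> ClusterScan:
    """Krzanowski-Lai cluster-number selection over k = 2..kmax-1.

    Chosen k = argmax KL(k); ties broken toward the smallest k.  k values
    whose DIFF_{k+1} vanishes are excluded with a warning, and a scan on
    structureless data is flagged low-confidence.
    """
    X, _ = _as_features(features, None)
    n, p = X.shape
    if kmax < 3:
        raise DataError("kmax must be >= 3 for a KL scan")
    if kmax > n - 1:
        raise DataError(f"kmax = {kmax} exceeds n - 1 = {n - 1}")
    wss = kmeans_wss(X, kmax, restarts=restarts, seed=seed)
    notes = []
    if np.any(np.diff(wss) > 1e-12):
        notes.append("W_k not non-increasing; consider more restarts")
    ex = 2.0 / p
    diff = {k: (k - 1) ** ex * wss[k - 2] - k**ex * wss[k - 1] for k in range(2, kmax + 1)}
    kl = {}
    for k in range(2, kmax):
        if diff[k + 1] == 0.0:
            notes.append(f"KL undefined at k={k} (DIFF_{k+1} = 0); excluded")
            continue
        kl[k] = abs(diff[k] / diff[k + 1])
    if not kl:
        raise DataError("KL index undefined for every candidate k")
    best = max(kl.values())
    chosen = min(k for k, v in kl.items() if v == best)
    low_conf = best < 2.0 or len(kl) < kmax - 2
    if low_conf:
        notes.append("weak cluster-number evidence (max KL < 2 or undefined entries)")
    for msg in notes:
        warnings.warn(msg, UserWarning, stacklevel=2)
    return ClusterScan(
        k_values=np.arange(1, kmax + 1), wss=wss, diff=diff, kl=kl,
        chosen_k=chosen, rule="krzanowski-lai", low_confidence=low_conf,
        warnings=tuple(notes),
    )


def elbow_select_k(wss_by_k) -> int:
    """Elbow rule: k with the largest second difference of W_k.

    ``wss_by_k`` is W_1..W_kmax; chosen k = argmax over interior k of
    (W_{k-1} - W_k) - (W_k - W_{k+1}), ties toward the smallest k.
    """
    w = np.asarray(wss_by_k, dtype=float)
    if w.size < 3:
        raise DataError("need W_k for k = 1..kmax with kmax >= 3")
    if np.any(np.diff(w) > 1e-12):
        warnings.warn("W_k is not non-increasing; elbow may be unreliable", UserWarning)
    second = (w[:-2] - w[1:-1]) - (w[1:-1] - w[2:])  # index i -> k = i + 2
    best = np.max(second)
    return int(np.argmax(second == best) + 2)
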
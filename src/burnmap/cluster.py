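"""K-means and bisecting K-means on small-dimension feature vectors.

Plain Lloyd K-means with k-means++-style seeding drives both entry points.
Bisecting K-means starts from a single cluster and repeatedly splits the
cluster with the highest sum of squared errors (SSE) via two-cluster
K-means until the requested K is reached — avoiding any fixed threshold
on the feature values.

Determinism: every run is reproducible from an integer seed. Seeding draws
are made over a canonical (lexicographic) ordering of the observations, so
shuffling the rows changes labels only by the induced permutation.

Empty clusters are repaired by moving the point farthest from its centroid
into the empty cluster, guaranteeing every cluster id has at least one
member (the severity stage relies on this).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_geodata import InputError

__all__ = ["ClusterResult", "kmeans", "bisecting_kmeans"]


@dataclass
class ClusterResult:
    """Labels, centroids and per-cluster SSE from a clustering run."""

    labels: np.ndarray          # (n,) int cluster ids in [0, K)
    centroids: np.ndarray       # (K, d)
    sse_per_cluster: np.ndarray  # (K,)
    n_iterations: int
    flags: list[str] = field(default_factory=list)
    sse_history: list[float] = field(default_factory=list)  # SSE after each assignment

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def total_sse(self) -> float:
        return float(self.sse_per_cluster.sum())


def _validate(X: np.ndarray, k: int) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise InputError("feature matrix must be 2-D (observations x features)")
    if not np.isfinite(X).all():
        raise InputError("feature matrix contains non-finite values")
    if k < 1:
        raise InputError("K must be at least 1")
    if X.shape[0] < k:
        raise InputError(f"need at least K={k} observations, got {X.shape[0]}")
    return X


def _canonical_order(X: np.ndarray) -> np.ndarray:
    """Row order keyed to the data values, invariant to input shuffling."""
    return np.lexsort(X.T[::-1])


def _seed_centroids(Xs: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding over canonically ordered rows."""
    n = Xs.shape[0]
    centroids = np.empty((k, Xs.shape[1]))
    first = rng.integers(n)
    centroids[0] = Xs[first]
    d2 = ((Xs - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = rng.integers(n)  # all points coincide with chosen centroids
        else:
            idx = int(np.searchsorted(np.cumsum(d2), rng.random() * total))
            idx = min(idx, n - 1)
        centroids[j] = Xs[idx]
        d2 = np.minimum(d2, ((Xs - centroids[j]) ** 2).sum(axis=1))
    return centroids


def _assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels and squared distances to the assigned centroid."""
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    return labels, d2[np.arange(X.shape[0]), labels]


def _sse_per_cluster(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    k = centroids.shape[0]
    d2 = ((X - centroids[labels]) ** 2).sum(axis=1)
    return np.bincount(labels, weights=d2, minlength=k)


def _repair_empty(X: np.ndarray, labels: np.ndarray, d2: np.ndarray, k: int) -> bool:
    """Move the farthest point from a multi-member cluster into each empty one.

    Mutates *labels* and *d2* in place; returns True if any repair happened.
    """
    repaired = False
    counts = np.bincount(labels, minlength=k)
    for empty in np.flatnonzero(counts == 0):
        eligible = counts[labels] >= 2
        if not eligible.any():
            continue
        candidates = np.flatnonzero(eligible)
        far = int(candidates[d2[candidates].argmax()])
        counts[labels[far]] -= 1
        labels[far] = empty
        counts[empty] += 1
        d2[far] = 0.0
        repaired = True
    return repaired


def kmeans(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterResult:
    """Lloyd K-means with k-means++ seeding; deterministic for a fixed seed.

    Convergence: maximum centroid movement below *tol* (feature units) or
    *max_iter* reached. Total SSE is non-increasing across iterations by
    construction of the Lloyd update.
    """
    X = _validate(X, k)
    rng = np.random.default_rng(seed)
    order = _canonical_order(X)
    centroids = _seed_centroids(X[order], k, rng)

    n_iter = 0
    flags: list[str] = []
    history: list[float] = []
    for n_iter in range(1, max_iter + 1):
        labels, d2 = _assign(X, centroids)
        history.append(float(d2.sum()))
        if _repair_empty(X, labels, d2, k):
            if "empty_cluster_repaired" not in flags:
                flags.append("empty_cluster_repaired")
        new_centroids = np.empty_like(centroids)
        for j in range(k):
            new_centroids[j] = X[labels == j].mean(axis=0)
        shift = np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max()
        centroids = new_centroids
        if shift < tol:
            break
    labels, d2 = _assign(X, centroids)
    if _repair_empty(X, labels, d2, k):
        if "empty_cluster_repaired" not in flags:
            flags.append("empty_cluster_repaired")
        for j in range(k):
            centroids[j] = X[labels == j].mean(axis=0)
    sse = _sse_per_cluster(X, labels, centroids)
    return ClusterResult(
        labels=labels,
        centroids=centroids,
        sse_per_cluster=sse,
        n_iterations=n_iter,
        flags=flags,
        sse_history=history,
    )


def bisecting_kmeans(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_trial_bisections: int = 5,
) -> ClusterResult:
    """Divisive clustering: split the highest-SSE cluster until K clusters exist.

    Each bisection runs two-cluster :func:`kmeans` *n_trial_bisections*
    times with derived seeds and keeps the split with the lowest SSE.
    Ties in highest-SSE selection break toward the lowest cluster id. If no
    cluster with more than one point remains, the run stops early with an
    ``early_stop`` flag and reports the K it achieved.
    """
    X = _validate(X, k)
    n = X.shape[0]
    labels = np.zeros(n, dtype=int)
    centroids = [X.mean(axis=0)]
    sse = [float(((X - centroids[0]) ** 2).sum())]
    flags: list[str] = []
    total_iter = 0
    split_counter = 0

    while len(centroids) < k:
        order = np.argsort(-np.asarray(sse), kind="stable")  # ties -> lowest id first
        target = next(
            (int(c) for c in order if np.sum(labels == c) >= 2),
            None,
        )
        if target is None:
            flags.append("early_stop")
            break
        members = np.flatnonzero(labels == target)
        sub = X[members]
        best: ClusterResult | None = None
        for t in range(n_trial_bisections):
            trial_seed = (seed + 7919 * split_counter + t) % (2**31)
            r = kmeans(sub, 2, seed=trial_seed, max_iter=max_iter, tol=tol)
            if best is None or r.total_sse < best.total_sse:
                best = r
        assert best is not None
        split_counter += 1
        total_iter += best.n_iterations
        new_id = len(centroids)
        labels[members[best.labels == 1]] = new_id
        centroids[target] = best.centroids[0]
        centroids.append(best.centroids[1])
        sse[target] = float(best.sse_per_cluster[0])
        sse.append(float(best.sse_per_cluster[1]))
        for f in best.flags:
            if f not in flags:
                flags.append(f)

    C = np.asarray(centroids)
    sse_arr = _sse_per_cluster(X, labels, C)
    return ClusterResult(
        labels=labels,
        centroids=C,
        sse_per_cluster=sse_arr,
        n_iterations=total_iter,
        flags=flags,
    )
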
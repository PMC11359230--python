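"""K-means / bisecting K-means against exhaustive-partition and
scikit-learn oracles, plus determinism and invariance properties."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from burnmap import InputError, bisecting_kmeans, kmeans


def exhaustive_best_sse(X: np.ndarray, k: int) -> float:
    """Exact optimal K-partition SSE by enumerating all label assignments."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    labelings = np.array(list(itertools.product(range(k), repeat=n)), dtype=np.int8)
    sq = (X**2).sum(axis=1)
    best = np.inf
    for c in range(k):
        member = labelings == c  # (m, n)
        cnt = member.sum(axis=1)
        valid = cnt > 0
        sx = member @ X  # (m, d)
        ssq = member @ sq  # (m,)
        sse_c = np.where(valid, ssq - (sx**2).sum(axis=1) / np.maximum(cnt, 1), np.inf)
        best = sse_c if c == 0 else best + sse_c
    # clusters must all be non-empty
    counts_ok = np.ones(len(labelings), dtype=bool)
    for c in range(k):
        counts_ok &= (labelings == c).any(axis=1)
    return float(best[counts_ok].min())


def blobs(n_per: int, centers, sigma: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    X = np.concatenate([c + sigma * rng.standard_normal((n_per, len(np.atleast_1d(c))))
                        for c in centers])
    y = np.repeat(np.arange(len(centers)), n_per)
    return X, y


class TestKmeans:
    def test_perfectly_separated_duplicates(self):
        r = kmeans(np.array([0.0, 0.0, 10.0, 10.0]), 2, seed=0)
        assert sorted(r.centroids.ravel()) == [0.0, 10.0]
        assert r.total_sse == 0.0

    def test_two_pair_partition(self):
        # brute force over all 2-partitions of {0, 2, 10, 12}: optimum pairs
        # the near points, SSE = 2 + 2
        X = np.array([0.0, 2.0, 10.0, 12.0])
        r = kmeans(X, 2, seed=0)
        assert r.total_sse == pytest.approx(4.0)
        assert r.total_sse == pytest.approx(exhaustive_best_sse(X, 2))
        assert r.labels[0] == r.labels[1] != r.labels[2]

    def test_k1_closed_form(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 3))
        r = kmeans(X, 1, seed=0)
        assert np.allclose(r.centroids[0], X.mean(axis=0))
        assert r.total_sse == pytest.approx(float(((X - X.mean(0)) ** 2).sum()))

    def test_preconditions(self):
        with pytest.raises(InputError):
            kmeans(np.zeros((2, 2)), 3)
        with pytest.raises(InputError):
            kmeans(np.array([[np.nan, 0.0]]), 1)

    def test_lloyd_sse_monotone_per_iteration(self):
        X, _ = blobs(60, [(0, 0), (1, 1), (3, 0)], 0.5, seed=5)
        for seed in range(5):
            r = kmeans(X, 3, seed=seed)
            h = np.asarray(r.sse_history)
            assert (np.diff(h) <= 1e-9).all()

    def test_determinism(self):
        X, _ = blobs(50, [(0, 0), (2, 2)], 0.3, seed=1)
        a = kmeans(X, 2, seed=42)
        b = kmeans(X, 2, seed=42)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)

    def test_permutation_invariance(self):
        X, _ = blobs(30, [(0, 0), (2, 2), (5, 5)], 0.2, seed=3)
        perm = np.random.default_rng(0).permutation(len(X))
        a = kmeans(X, 3, seed=7)
        b = kmeans(X[perm], 3, seed=7)
        assert a.total_sse == pytest.approx(b.total_sse)
        # identical partition up to the induced permutation
        for c in np.unique(a.labels[perm]):
            members = a.labels[perm] == c
            assert len(np.unique(b.labels[members])) == 1

    def test_empty_cluster_repair_keeps_all_clusters_populated(self):
        X = np.zeros((6, 2))  # all points identical
        r = kmeans(X, 3, seed=0)
        assert set(r.labels) == {0, 1, 2}
        assert "empty_cluster_repaired" in r.flags

    def test_matches_sklearn_on_separated_blobs(self):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        X, _ = blobs(80, [(0, 0), (4, 4), (8, 0)], 0.3, seed=9)
        ours = kmeans(X, 3, seed=0)
        ref = sklearn_cluster.KMeans(3, n_init=10, random_state=0).fit(X)
        assert ours.total_sse == pytest.approx(ref.inertia_, rel=1e-6)


class TestBisecting:
    def test_k2_equals_plain_kmeans_partition(self):
        X, _ = blobs(40, [(0, 0), (3, 3)], 0.3, seed=4)
        b = bisecting_kmeans(X, 2, seed=0)
        k = kmeans(X, 2, seed=0)
        assert b.total_sse == pytest.approx(k.total_sse, rel=1e-9)

    def test_three_pairs_exact(self):
        X = np.array([0.0, 1.0, 10.0, 11.0, 20.0, 21.0])
        r = bisecting_kmeans(X, 3, seed=0)
        assert r.total_sse == pytest.approx(1.5)
        assert r.total_sse == pytest.approx(exhaustive_best_sse(X, 3))

    def test_two_tight_blobs_zero_errors(self):
        X, y = blobs(100, [(0.0, 0.0), (1.0, 0.0)], 0.01, seed=6)
        r = bisecting_kmeans(X, 2, seed=0)
        # partition must match generating labels exactly (up to label swap)
        same = (r.labels == y).mean()
        assert same in (0.0, 1.0)

    @pytest.mark.parametrize("n,k,d,seed", [
        (8, 2, 1, 0), (9, 3, 1, 1), (10, 2, 2, 2), (12, 3, 2, 3), (7, 3, 2, 4),
    ])
    def test_exact_optimum_on_well_separated_small_instances(self, n, k, d, seed):
        # separation / sigma >= 10 -> bisecting result is exactly optimal
        rng = np.random.default_rng(seed)
        centers = [np.full(d, 10.0 * c) for c in range(k)]
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        X = np.concatenate(
            [c + 0.5 * rng.standard_normal((s, d)) for c, s in zip(centers, sizes)]
        )
        r = bisecting_kmeans(X, k, seed=seed)
        assert r.total_sse == pytest.approx(exhaustive_best_sse(X, k), rel=1e-9)

    def test_total_sse_non_increasing_in_k(self):
        X, _ = blobs(50, [(0, 0), (3, 0), (0, 3), (3, 3)], 0.4, seed=8)
        sses = [bisecting_kmeans(X, k, seed=0).total_sse for k in range(1, 6)]
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))

    def test_singleton_clusters_skipped_for_next_splittable(self):
        # after the first split {0} has SSE 0 and size 1; the tie in SSE
        # selection must skip it and bisect the splittable cluster instead
        X = np.array([0.0, 5.0, 5.0, 5.0])
        r = bisecting_kmeans(X, 3, seed=0)
        assert r.k == 3
        assert set(r.labels) == {0, 1, 2}
        assert "early_stop" not in r.flags

    def test_k_equals_n_yields_singletons(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        r = bisecting_kmeans(X, 3, seed=0)
        assert r.k == 3
        assert r.total_sse == pytest.approx(0.0)

    def test_determinism(self):
        X, _ = blobs(60, [(0, 0), (2, 2), (4, 0)], 0.3, seed=10)
        a = bisecting_kmeans(X, 3, seed=5)
        b = bisecting_kmeans(X, 3, seed=5)
        assert np.array_equal(a.labels, b.labels)

    def test_every_cluster_nonempty_and_sse_consistent(self):
        X, _ = blobs(70, [(0, 0), (2, 2), (5, 1)], 0.5, seed=12)
        r = bisecting_kmeans(X, 3, seed=0)
        assert set(r.labels) == {0, 1, 2}
        assert r.total_sse == pytest.approx(float(r.sse_per_cluster.sum()))
        # for plain kmeans each observation sits with its nearest centroid at
        # convergence (the divisive hierarchy only guarantees this per split)
        k = kmeans(X, 3, seed=0)
        d2 = ((X[:, None, :] - k.centroids[None]) ** 2).sum(axis=2)
        assert np.array_equal(d2.argmin(axis=1), k.labels)
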
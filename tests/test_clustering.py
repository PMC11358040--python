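import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from trsaxs.cluster import (
    elbow_select_k,
    kl_select_k,
    kmeans_cluster,
    kmeans_wss,
    single_linkage_cluster,
)
from trsaxs.errors import DataError


def naive_single_linkage(X, k):
    """O(n^3) pairwise-minimum agglomeration oracle; ties by smallest index."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    clusters = [[i] for i in range(len(X))]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(np.linalg.norm(X[i] - X[j])
                        for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(X), int)
    for cid, members in enumerate(clusters):
        labels[members] = cid
    return labels


def planted_gaussians(rng, centers, n_per=5, sd=0.1):
    pts, labels = [], []
    for ci, c in enumerate(centers):
        pts.append(rng.normal(0, sd, (n_per, len(c))) + np.asarray(c))
        labels += [ci] * n_per
    return np.vstack(pts), np.asarray(labels)


class TestSingleLinkage:
    def test_obvious_1d_split(self):
        assign, _ = single_linkage_cluster(np.array([0.0, 1.0, 10.0]), k=2,
                                           labels=["a", "b", "c"])
        assert assign.assignment["a"] == assign.assignment["b"] != assign.assignment["c"]

    def test_k_equals_n_gives_singletons(self):
        assign, _ = single_linkage_cluster(np.arange(5.0), k=5)
        assert sorted(assign.assignment.values()) == [1, 2, 3, 4, 5]

    def test_k_one_returns_single_cluster(self):
        assign, _ = single_linkage_cluster(np.random.default_rng(0).normal(size=(6, 2)), k=1)
        assert set(assign.assignment.values()) == {1}

    def test_planted_clusters_match_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        X, truth = planted_gaussians(rng, [(0, 0), (10, 0), (0, 10), (10, 10)], sd=0.1)
        assign, _ = single_linkage_cluster(X, k=4)
        got = assign.ids_for([str(i) for i in range(len(X))])
        assert adjusted_rand_score(truth, got) == 1.0
        oracle = naive_single_linkage(X, 4)
        assert adjusted_rand_score(oracle, got) == 1.0

    def test_k_exceeding_n_is_error(self):
        with pytest.raises(DataError):
            single_linkage_cluster(np.arange(3.0), k=4)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X, _ = planted_gaussians(rng, [(0,), (8,)], n_per=4)
        labels = [f"s{i}" for i in range(len(X))]
        a1, _ = single_linkage_cluster(X, k=2, labels=labels)
        perm = rng.permutation(len(X))
        a2, _ = single_linkage_cluster(X[perm], k=2, labels=[labels[i] for i in perm])
        groups1 = {}
        groups2 = {}
        for l in labels:
            groups1.setdefault(a1.assignment[l], set()).add(l)
            groups2.setdefault(a2.assignment[l], set()).add(l)
        assert set(map(frozenset, groups1.values())) == set(map(frozenset, groups2.values()))


class TestKMeans:
    def test_two_tight_1d_groups(self):
        assign = kmeans_cluster(np.array([0.0, 0.1, 10.0, 10.1]), k=2, seed=0)
        assert assign.assignment["0"] == assign.assignment["1"]
        assert assign.assignment["2"] == assign.assignment["3"]
        assert assign.inertia == pytest.approx(0.01)

    def test_k1_inertia_is_total_ss(self):
        x = np.array([1.0, 2.0, 4.0, 9.0])
        wss = kmeans_wss(x, kmax=1)
        assert wss[0] == pytest.approx(np.sum((x - x.mean()) ** 2))

    def test_planted_four_clusters_recovered(self):
        rng = np.random.default_rng(8)
        X, truth = planted_gaussians(rng, [(0, 0), (10, 0), (0, 10), (10, 10)], sd=0.1)
        assign = kmeans_cluster(X, k=4, seed=3)
        got = assign.ids_for([str(i) for i in range(len(X))])
        assert adjusted_rand_score(truth, got) == 1.0
        # oracle: W of the planted partition is the optimum this solver must reach
        w_planted = sum(np.sum((X[truth == c] - X[truth == c].mean(axis=0)) ** 2)
                        for c in range(4))
        assert assign.inertia == pytest.approx(w_planted, rel=1e-9)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        X, _ = planted_gaussians(rng, [(0, 0), (5, 5), (9, 0)], sd=0.5)
        a1 = kmeans_cluster(X, k=3, seed=11)
        a2 = kmeans_cluster(X, k=3, seed=11)
        assert a1.assignment == a2.assignment and a1.inertia == a2.inertia


class TestKrzanowskiLai:
    def test_six_point_example_chooses_two(self):
        # oracle (hand arithmetic on exact k-means partitions of this set):
        # W = {150.04, 0.04, 0.025, 0.01}; DIFF_2..4 = {149.88, -0.065, 0.065};
        # KL(2) = 2305.85, KL(3) = 1.0 -> k = 2
        x = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
        scan = kl_select_k(x, kmax=4, seed=0)
        np.testing.assert_allclose(scan.wss, [150.04, 0.04, 0.025, 0.01], rtol=1e-9)
        assert scan.diff[2] == pytest.approx(149.88, rel=1e-9)
        assert scan.diff[3] == pytest.approx(-0.065, rel=1e-9)
        assert scan.diff[4] == pytest.approx(0.065, rel=1e-9)
        assert scan.kl[2] == pytest.approx(149.88 / 0.065, rel=1e-9)
        assert scan.kl[3] == pytest.approx(1.0, rel=1e-9)
        assert scan.chosen_k == 2

    def test_planted_four_groups_choose_four(self):
        rng = np.random.default_rng(17)
        X, _ = planted_gaussians(rng, [(0, 0), (10, 0), (0, 10), (10, 10)],
                                 n_per=4, sd=0.1)
        scan = kl_select_k(X, kmax=6, seed=1)
        assert scan.chosen_k == 4

    def test_structureless_data_flags_low_confidence(self):
        x = np.linspace(0.0, 1.0, 12)
        with pytest.warns(UserWarning):
            scan = kl_select_k(x, kmax=5, seed=0)
        assert scan.low_confidence

    def test_kmax_bounds(self):
        with pytest.raises(DataError):
            kl_select_k(np.arange(6.0), kmax=2, seed=0)
        with pytest.raises(DataError):
            kl_select_k(np.arange(4.0), kmax=4, seed=0)


class TestElbow:
    def test_textbook_example(self):
        assert elbow_select_k([100.0, 20.0, 18.0, 17.0]) == 2

    def test_linear_decline_ties_to_smallest_interior_k(self):
        assert elbow_select_k([40.0, 30.0, 20.0, 10.0, 0.0]) == 2

    def test_planted_two_groups_via_kmeans_wss(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.05, 6), rng.normal(5, 0.05, 6)])
        wss = kmeans_wss(x, kmax=4, seed=2)
        assert elbow_select_k(wss) == 2
        # oracle: W_2 computed by hand from the obvious optimal partition
        w2 = np.sum((x[:6] - x[:6].mean()) ** 2) + np.sum((x[6:] - x[6:].mean()) ** 2)
        assert wss[1] == pytest.approx(w2, rel=1e-9)

    def test_non_monotone_warns(self):
        with pytest.warns(UserWarning):
            elbow_select_k([10.0, 12.0, 5.0, 4.0])
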
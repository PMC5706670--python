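"""Agglomeration, multiscale-bootstrap BP/AU, significant clusters, Newick."""

import numpy as np
import pandas as pd
import pytest

from ctcseq.clustering import (
    ClusteringError,
    _fit_au,
    hierarchical_cluster,
    multiscale_bootstrap,
    significant_clusters,
    spearman_distance,
    to_newick,
)


def test_average_linkage_hand_example():
    D = pd.DataFrame(
        [[0, 1, 4], [1, 0, 5], [4, 5, 0]],
        index=list("ABC"), columns=list("ABC"), dtype=float,
    )
    tree = hierarchical_cluster(D)
    (a, b, h1), (x, y, h2) = tree.merges
    assert {a, b} == {0, 1} and h1 == pytest.approx(1.0)
    assert h2 == pytest.approx(4.5)  # average of d(A,C)=4, d(B,C)=5


def test_equal_distances_merge_deterministically():
    n = 5
    D = np.ones((n, n)) - np.eye(n)
    t1 = hierarchical_cluster(D, labels=list("ABCDE"))
    t2 = hierarchical_cluster(D, labels=list("ABCDE"))
    assert t1.merges == t2.merges
    assert all(h == pytest.approx(1.0) for _, _, h in t1.merges)
    # first merge takes the lexicographically smallest active pair
    assert t1.merges[0][:2] == (0, 1)


def test_duplicated_profiles_merge_at_height_zero():
    D = np.array([[0.0, 0.0, 2.0], [0.0, 0.0, 2.0], [2.0, 2.0, 0.0]])
    tree = hierarchical_cluster(D)
    assert tree.merges[0][2] == 0.0


def test_missing_distances_imputed_as_matrix_max():
    D = np.array([[0.0, np.nan, 1.0], [np.nan, 0.0, 3.0], [1.0, 3.0, 0.0]])
    tree = hierarchical_cluster(D, labels=list("ABC"))
    assert tree.n_imputed_distances == 2
    assert tree.merges[0][:2] == (0, 2)  # d(A,C)=1 is now the minimum


def test_fewer_than_two_leaves_is_error():
    with pytest.raises(ClusteringError):
        hierarchical_cluster(np.zeros((1, 1)))


def test_merge_heights_match_scipy_average_linkage(rng):
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    for _ in range(10):
        X = rng.normal(size=(12, 7))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        ours = hierarchical_cluster(D)
        Z = linkage(squareform(D, checks=False), method="average")
        assert np.allclose(sorted(h for _, _, h in ours.merges), sorted(Z[:, 2]))
        # leaf sets of internal nodes agree (no ties in random data)
        def scipy_leafsets(Z, n):
            sets = {i: frozenset([i]) for i in range(n)}
            out = set()
            for k, row in enumerate(Z):
                s = sets[int(row[0])] | sets[int(row[1])]
                sets[n + k] = s
                out.add(s)
            return out

        ours_sets = {ours.leafset(nid) for nid in ours.internal_ids}
        assert ours_sets == scipy_leafsets(Z, 12)


# ------------------------------------------------------- multiscale bootstrap

def _two_group_features(rng, n_per=6, f=24, sep=4.0, noise=1.0):
    X = rng.normal(scale=noise, size=(f, 2 * n_per))
    X[: f // 2, :n_per] += sep
    labels = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    return X, labels


def euclidean_distance(X):
    X = np.asarray(X, dtype=float)
    diff = X.T[:, None, :] - X.T[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def test_bp_at_scale_one_matches_plain_bootstrap_oracle(rng):
    """BP at r=1 equals an independent scipy-based bootstrap proportion."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    X, labels = _two_group_features(rng, n_per=5, f=30, sep=1.5, noise=1.0)
    B = 400
    tree = multiscale_bootstrap(
        X, euclidean_distance, scales=[1.0], B=B, seed=5, labels=labels
    )
    # independent oracle: resample features, cluster with scipy, count leaf sets
    n = len(labels)
    oracle_rng = np.random.default_rng(99)
    counts = {tree.leafset(nid): 0 for nid in tree.internal_ids}
    for _ in range(B):
        idx = oracle_rng.integers(0, X.shape[0], X.shape[0])
        D = euclidean_distance(X[idx])
        Z = linkage(squareform(D, checks=False), method="average")
        sets = {i: frozenset([i]) for i in range(n)}
        reps = set()
        for k, row in enumerate(Z):
            s = sets[int(row[0])] | sets[int(row[1])]
            sets[n + k] = s
            reps.add(s)
        for s in reps:
            if s in counts:
                counts[s] += 1
    for nid in tree.internal_ids:
        bp = tree.bp_by_scale[nid][1.0]
        p_oracle = counts[tree.leafset(nid)] / B
        p = (bp + p_oracle) / 2
        sd = np.sqrt(max(p * (1 - p), 1e-12) * 2 / B)
        assert abs(bp - p_oracle) <= max(3 * sd, 0.02)


def test_perfectly_separated_groups_have_au_100(rng):
    X, labels = _two_group_features(rng, n_per=5, f=20, sep=50.0, noise=0.01)
    tree = multiscale_bootstrap(X, euclidean_distance, B=200, seed=3, labels=labels)
    ga = frozenset(l for l in labels if l.startswith("a"))
    gb = frozenset(l for l in labels if l.startswith("b"))
    found = {tree.leaf_names(nid): tree.au[nid] for nid in tree.internal_ids}
    assert found[ga] == 100.0 and found[gb] == 100.0


def test_all_lower_clamped_bp_gives_au_zero():
    D = np.array(
        [[0, 1, 2, 3], [1, 0, 2.5, 3.5], [2, 2.5, 0, 1.2], [3, 3.5, 1.2, 0.0]]
    )
    tree = hierarchical_cluster(D, labels=list("ABCD"))
    scales = [0.5, 1.0, 1.4]
    tree.bp_by_scale = {
        nid: {r: 0.0 for r in scales} for nid in tree.internal_ids
    }
    _fit_au(tree, scales, B=100)
    for nid in tree.internal_ids:
        assert tree.au[nid] == 0.0


def test_same_seed_gives_identical_bp_tables(rng):
    X, labels = _two_group_features(rng, n_per=4, f=16, sep=2.0)
    t1 = multiscale_bootstrap(X, euclidean_distance, scales=[0.6, 1.0], B=120,
                              seed=42, labels=labels)
    t2 = multiscale_bootstrap(X, euclidean_distance, scales=[0.6, 1.0], B=120,
                              seed=42, labels=labels)
    assert t1.bp_by_scale == t2.bp_by_scale
    assert t1.au == t2.au


def test_too_few_features_is_error(rng):
    X = rng.normal(size=(5, 6))
    with pytest.raises(ClusteringError):
        multiscale_bootstrap(X, euclidean_distance, B=100, seed=1)


def test_bp_values_are_proportions(rng):
    X, labels = _two_group_features(rng, n_per=4, f=18, sep=1.0)
    tree = multiscale_bootstrap(X, euclidean_distance, scales=[0.5, 1.0], B=100,
                                seed=8, labels=labels)
    for nid in tree.internal_ids:
        for r, v in tree.bp_by_scale[nid].items():
            assert 0.0 <= v <= 1.0
        assert 0.0 <= tree.au[nid] <= 100.0


# --------------------------------------------------- significant clusters

def _tree_with_au(au_by_leafset):
    D = np.array(
        [
            [0, 1, 5, 5, 9, 9],
            [1, 0, 5, 5, 9, 9],
            [5, 5, 0, 1, 9, 9],
            [5, 5, 1, 0, 9, 9],
            [9, 9, 9, 9, 0, 1],
            [9, 9, 9, 9, 1, 0],
        ],
        dtype=float,
    )
    tree = hierarchical_cluster(D, labels=list("ABCDEF"))
    for nid in tree.internal_ids:
        tree.au[nid] = au_by_leafset.get(tree.leaf_names(nid), 0.0)
    return tree


def test_significant_clusters_maximality_and_root_exclusion():
    tree = _tree_with_au(
        {
            frozenset("AB"): 100.0,
            frozenset("ABCD"): 96.0,
            frozenset("EF"): 100.0,
            frozenset("ABCDEF"): 100.0,  # root: excluded
        }
    )
    sig = significant_clusters(tree, alpha=0.05)
    assert sorted(map(sorted, sig)) == [["A", "B", "C", "D"], ["E", "F"]]


def test_no_node_above_threshold_gives_empty_list():
    tree = _tree_with_au({frozenset("AB"): 80.0})
    assert significant_clusters(tree, alpha=0.05) == []


# ------------------------------------------------------------------- newick

def test_newick_two_leaves_shape():
    tree = hierarchical_cluster(np.array([[0.0, 2.0], [2.0, 0.0]]), labels=["A", "B"])
    assert to_newick(tree, au_labels=False) == "(A:2,B:2);"


def test_newick_round_trip_topology(rng):
    import dendropy

    n = 10
    X = rng.normal(size=(n, 4))
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    labels = [f"L{i}" for i in range(n)]
    tree = hierarchical_cluster(D, labels=labels)
    parsed = dendropy.Tree.get(data=to_newick(tree, au_labels=False), schema="newick")
    got = {
        frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        for node in parsed.preorder_node_iter()
        if not node.is_leaf()
    }
    expected = {frozenset(tree.leaf_names(nid)) for nid in tree.internal_ids}
    assert got == expected


def test_newick_carries_au_labels(rng):
    X, labels = _two_group_features(rng, n_per=3, f=15, sep=40.0, noise=0.01)
    tree = multiscale_bootstrap(X, euclidean_distance, scales=[1.0], B=100,
                                seed=2, labels=labels)
    nwk = to_newick(tree)
    assert ")100:" in nwk


def test_spearman_distance_agrees_with_statistic():
    from ctcseq.expression import spearman

    rng = np.random.default_rng(12)
    X = rng.normal(size=(20, 4))
    D = spearman_distance(X)
    assert D[1, 2] == pytest.approx(1.0 - spearman(X[:, 1], X[:, 2]), abs=1e-12)
    assert np.allclose(np.diag(D), 0.0)
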
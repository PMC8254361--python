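"""SHscore core: distances, per-cell sh, partitions, scan, heatmap."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from spathet import (CNVMatrix, Partition, PartitionError, aggregate,
                     aggregate_heatmap, cell_sh, enumerate_partitions,
                     mean_intra_distance, min_mean_inter_distance,
                     pairwise_distance, partition_scan, shscore,
                     shscore_from_distances, silhouette_from_distances)

from conftest import make_matrix


def brute_force_sh(X, labels):
    """Independent silhouette-with-L1 oracle: explicit double loops."""
    n = len(X)
    D = [[sum(abs(float(a) - float(b)) for a, b in zip(X[i], X[j]))
          for j in range(n)] for i in range(n)]
    out = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            out.append(0.0)
            continue
        a = sum(D[i][j] for j in own) / len(own)
        b = min(sum(D[i][j] for j in range(n) if labels[j] == lab)
                / sum(1 for j in range(n) if labels[j] == lab)
                for lab in set(labels) - {labels[i]})
        m = max(a, b)
        out.append(0.0 if m == 0 else (b - a) / m)
    return np.array(out)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_l1_distance_hand_examples():
    D = pairwise_distance(np.array([[2, 3], [4, 1]])).values
    assert D[0, 1] == 4
    D = pairwise_distance(np.array([[2, 2], [2, 2]])).values
    assert D[0, 1] == 0


def test_l1_distance_matches_double_loop(rng):
    X = rng.integers(0, 8, size=(7, 11))
    D = pairwise_distance(X).values
    for i in range(7):
        for j in range(7):
            assert D[i, j] == np.abs(X[i] - X[j]).sum()
    assert np.array_equal(D, D.T)
    assert np.all(np.diag(D) == 0)


def test_distance_requires_two_cells():
    with pytest.raises(ValueError):
        pairwise_distance(np.array([[2, 2]]))
    with pytest.raises(ValueError):
        pairwise_distance(np.array([[2], [2]]), metric="euclidean")


# ---------------------------------------------------------------------------
# a(p), b(p), sh(p)
# ---------------------------------------------------------------------------

def test_mean_intra_distance_hand_example():
    # one-bin cells [2], [3], [5] in one block: a([2]) = (1 + 3) / 2
    D = pairwise_distance(np.array([[2], [3], [5]]))
    labels = ["A", "A", "A"]
    assert mean_intra_distance(0, labels, D) == 2.0


def test_mean_intra_distance_identical_and_pair():
    D = pairwise_distance(np.array([[2], [2], [7]]))
    assert mean_intra_distance(0, ["A", "A", "B"], D) == 0.0
    assert mean_intra_distance(2, ["A", "B", "B"], D) == 5.0
    with pytest.raises(PartitionError):
        mean_intra_distance(2, ["A", "A", "B"], D)  # singleton block


def test_min_mean_inter_distance_takes_minimum():
    # cell 0 vs block B (mean 5) and block C (mean 3)
    X = np.array([[0], [5], [5], [3], [3]])
    D = pairwise_distance(X)
    labels = ["A", "B", "B", "C", "C"]
    assert min_mean_inter_distance(0, labels, D) == 3.0
    assert min_mean_inter_distance(1, ["A", "B", "B", "B", "B"], D) == 5.0
    with pytest.raises(PartitionError):
        min_mean_inter_distance(0, ["A"] * 5, D)


def test_min_mean_inter_matches_bruteforce(rng):
    X = rng.integers(0, 6, size=(10, 4))
    labels = list("AABBBCCCCA")
    D = pairwise_distance(X)
    for p in range(10):
        expected = min(
            np.mean([np.abs(X[p] - X[q]).sum()
                     for q in range(10) if labels[q] == lab])
            for lab in set(labels) - {labels[p]})
        assert min_mean_inter_distance(p, labels, D) == pytest.approx(expected)


@pytest.mark.parametrize("a,b,expected", [
    (0.0, 2.0, 1.0),
    (2.0, 1.0, -0.5),
    (3.0, 3.0, 0.0),
    (0.0, 0.0, 0.0),
])
def test_cell_sh(a, b, expected):
    assert cell_sh(a, b) == expected


def test_cell_sh_rejects_negative():
    with pytest.raises(ValueError):
        cell_sh(-1.0, 2.0)


# ---------------------------------------------------------------------------
# SHscore
# ---------------------------------------------------------------------------

def test_shscore_perfect_separation():
    m = make_matrix(np.array([[2], [2], [4], [4]]),
                    labels=["S1", "S1", "S2", "S2"])
    res = shscore(m)
    assert res.score == 1.0
    assert np.all(res.per_cell_sh == 1.0)


def test_shscore_mirrored_construction():
    # each cell: a = 2 (its own sample's other cell differs by 2),
    # b = 1 (mean distance 0 and 2 to the other sample) => sh = -0.5
    m = make_matrix(np.array([[2], [4], [2], [4]]),
                    labels=["S1", "S1", "S2", "S2"])
    res = shscore(m)
    assert res.score == -0.5
    assert np.all(res.per_cell_sh == -0.5)


def test_shscore_matches_sklearn_silhouette(rng):
    """Same distances as the generic silhouette with sample labels as clusters."""
    for _ in range(5):
        n = int(rng.integers(10, 50))
        X = rng.integers(0, 8, size=(n, 20))
        labels = rng.choice(["A", "B", "C"], size=n)
        if len(set(labels)) < 2:
            continue
        m = make_matrix(X, labels=labels)
        res = shscore(m)
        ref = silhouette_samples(X.astype(float), labels, metric="manhattan")
        assert np.allclose(res.per_cell_sh, ref, atol=1e-12)


def test_shscore_matches_bruteforce(rng):
    n = 18
    X = rng.integers(0, 6, size=(n, 5))
    labels = rng.choice(["A", "B"], size=n)
    m = make_matrix(X, labels=labels)
    assert np.allclose(shscore(m).per_cell_sh, brute_force_sh(X, list(labels)),
                       atol=1e-12)


def test_singleton_sample_contributes_zero():
    m = make_matrix(np.array([[2], [4], [4]]), labels=["S1", "S2", "S2"])
    res = shscore(m)
    assert res.per_cell_sh[0] == 0.0


@given(st.integers(0, 2**31 - 1))
def test_sh_bounds_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 16))
    X = rng.integers(0, 6, size=(n, 3))
    labels = rng.integers(0, 3, size=n)
    if len(np.unique(labels)) < 2:
        labels[0] = 0
        labels[1] = 1
    D = pairwise_distance(X)
    sh = silhouette_from_distances(D, labels)
    assert np.all(sh >= -1.0) and np.all(sh <= 1.0)


@given(st.integers(1, 50))
def test_scale_invariance(factor):
    rng = np.random.default_rng(99)
    X = rng.integers(0, 6, size=(12, 8))
    labels = rng.choice(["A", "B", "C"], size=12)
    labels[:2] = ["A", "B"]
    base = silhouette_from_distances(pairwise_distance(X), labels)
    scaled = silhouette_from_distances(pairwise_distance(X * factor), labels)
    assert np.allclose(base, scaled, atol=1e-12)


def test_label_permutation_null(rng):
    """Random labels on one homogeneous population score near zero."""
    X = np.full((60, 40), 2) + rng.integers(0, 3, size=(60, 40))
    D = pairwise_distance(X)
    scores = [shscore_from_distances(D, rng.integers(0, 3, size=60))
              for _ in range(20)]
    assert abs(np.median(scores)) < 0.05


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

def test_three_samples_give_four_partitions():
    parts = enumerate_partitions(["s1", "s2", "s3"])
    names = {p.name for p in parts}
    assert names == {"s1 vs s2 vs s3", "s1+s2 vs s3", "s1+s3 vs s2",
                     "s1 vs s2+s3"}


@pytest.mark.parametrize("n,expected", [(2, 1), (3, 4), (4, 14)])
def test_partition_counts_are_bell_minus_one(n, expected):
    samples = [f"s{i}" for i in range(n)]
    parts = enumerate_partitions(samples)
    assert len(parts) == expected
    for p in parts:
        assert p.samples == set(samples)
        assert sum(len(b) for b in p.blocks) == n  # disjoint cover


def test_partition_cap_and_override():
    many = [f"s{i}" for i in range(7)]
    with pytest.raises(PartitionError):
        enumerate_partitions(many)
    parts = enumerate_partitions(many, allow_large=True)
    assert len(parts) == 876  # Bell(7) - 1


def test_partition_validation():
    with pytest.raises(PartitionError):
        Partition.from_blocks([["a", "b"]])
    with pytest.raises(PartitionError):
        Partition.from_blocks([["a"], ["a", "b"]])
    m = make_matrix(np.array([[2], [4]]), labels=["A", "B"])
    with pytest.raises(PartitionError):
        shscore(m, Partition.from_blocks([["A"], ["X"]]))


def test_partition_scan_separated_clones(rng):
    a = make_matrix(2 + rng.integers(0, 2, size=(10, 30)), labels="A")
    b = make_matrix(8 + rng.integers(0, 2, size=(10, 30)), labels="B", prefix="d")
    scan = partition_scan(aggregate([a, b], ["A", "B"]))
    assert scan.best.name == "A vs B"
    assert scan.best_result.score > 0.9


def test_partition_scan_merges_iid_samples(rng):
    """Two i.i.d. samples from one clone are best scored as one block."""
    clone1 = lambda n: 2 + rng.integers(0, 2, size=(n, 40))
    clone2 = lambda n: 7 + rng.integers(0, 2, size=(n, 40))
    m = aggregate([make_matrix(clone1(12), prefix="x"),
                   make_matrix(clone1(12), prefix="y"),
                   make_matrix(clone2(12), prefix="z")], ["s1", "s2", "s3"])
    scan = partition_scan(m)
    assert scan.best.name == "s1+s2 vs s3"
    # merged score beats the all-separate score
    table = scan.table.set_index("partition")["score"]
    assert table["s1+s2 vs s3"] > table["s1 vs s2 vs s3"]


def test_partition_scan_reports_all_partitions_sorted(rng):
    m = aggregate([make_matrix(rng.integers(0, 5, size=(5, 10)), prefix=p)
                   for p in "xyz"], ["a", "b", "c"])
    scan = partition_scan(m)
    assert len(scan.table) == 4
    scores = scan.table["score"].to_numpy()
    assert np.all(np.diff(scores) <= 0)
    assert set(scan.table["interpretation"]) <= {"segregated", "well-mixed"}


# ---------------------------------------------------------------------------
# heatmap
# ---------------------------------------------------------------------------

def test_heatmap_top_split_matches_clones(tmp_path, rng):
    import matplotlib.pyplot as plt

    a = make_matrix(2 + rng.integers(0, 2, size=(8, 25)), labels="A")
    b = make_matrix(9 + rng.integers(0, 2, size=(8, 25)), labels="B", prefix="d")
    m = aggregate([a, b], ["A", "B"])
    out = tmp_path / "heat.png"
    order, fig = aggregate_heatmap(m, out=out)
    assert out.stat().st_size > 0
    D = pairwise_distance(m)
    Z = hierarchy.linkage(squareform(D.values, checks=False), method="ward")
    top2 = hierarchy.fcluster(Z, 2, criterion="maxclust")
    assert adjusted_rand_score(m.sample_labels, top2) == 1.0
    plt.close(fig)


def test_heatmap_homogeneous_data_mixes_samples(tmp_path, rng):
    import matplotlib.pyplot as plt

    X = 2 + rng.integers(0, 3, size=(16, 25))
    labels = rng.permutation(["A"] * 8 + ["B"] * 8)
    m = make_matrix(X, labels=labels)
    order, fig = aggregate_heatmap(m)
    D = pairwise_distance(m)
    Z = hierarchy.linkage(squareform(D.values, checks=False), method="ward")
    top2 = hierarchy.fcluster(Z, 2, criterion="maxclust")
    assert adjusted_rand_score(m.sample_labels, top2) < 0.5
    plt.close(fig)
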
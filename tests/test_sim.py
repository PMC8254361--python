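"""Simulator: tree growth, event model, scenarios, MRCA distances."""

import numpy as np
import pytest

from spathet import (CNAEvent, SimulationConfig, SimulationError,
                     apply_event, mrca_distance, reduced_genome, scenario_het,
                     scenario_hom, scenario_metastasis, scenario_var,
                     shscore_from_distances, pairwise_distance,
                     simulate_tree, subtree_samples)
from spathet.sim import _sample_event


@pytest.fixture(scope="module")
def genome():
    return reduced_genome()


@pytest.fixture(scope="module")
def small_tree(genome):
    return simulate_tree(SimulationConfig(n_leaves=64, genome=genome, seed=5))


def cfg(genome, n_leaves=64, **kw):
    return SimulationConfig(n_leaves=n_leaves, genome=genome, **kw)


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def test_two_leaf_tree_is_root_with_two_children(genome):
    t = simulate_tree(cfg(genome, n_leaves=2))
    assert t.n_nodes == 3
    assert t.children[0] == [1, 2]
    assert t.is_leaf(1) and t.is_leaf(2)


def test_binary_node_count(genome):
    t = simulate_tree(cfg(genome, n_leaves=200, seed=1))
    assert t.n_leaves == 200
    assert t.n_nodes == 2 * 200 - 1  # binary tree: n-1 internal nodes


def test_same_seed_bitwise_identical(genome):
    a = simulate_tree(cfg(genome, seed=42))
    b = simulate_tree(cfg(genome, seed=42))
    assert a.parent == b.parent
    assert a.division_order == b.division_order
    assert np.array_equal(a.leaves_to_matrix().X, b.leaves_to_matrix().X)


def test_config_validation(genome):
    with pytest.raises(SimulationError):
        SimulationConfig(n_leaves=1, genome=genome)
    with pytest.raises(SimulationError):
        SimulationConfig(n_leaves=10, genome=genome, gain_p=0)
    with pytest.raises(SimulationError):
        SimulationConfig(n_leaves=10, genome=genome, theta=1e12)


# ---------------------------------------------------------------------------
# event model
# ---------------------------------------------------------------------------

def test_apply_event_gain_loss_floor(genome):
    state = np.full(genome.n_bins, 2, dtype=np.int32)
    gained = apply_event(state, CNAEvent("chr1", 0, 250_000, +2), genome)
    assert list(gained[:4]) == [4, 4, 4, 2]
    lost = apply_event(state, CNAEvent("chr1", 0, 150_000, -3), genome)
    assert list(lost[:3]) == [0, 0, 2]  # floored at zero, never negative
    regained = apply_event(lost, CNAEvent("chr1", 0, 150_000, +5), genome)
    assert list(regained[:3]) == [0, 0, 2]  # deleted bins immune to gains


def test_apply_event_out_of_range(genome):
    state = np.full(genome.n_bins, 2, dtype=np.int32)
    with pytest.raises(SimulationError):
        apply_event(state, CNAEvent("chr1", 99_999_999, 10_000, 1), genome)
    with pytest.raises(SimulationError):
        apply_event(state, CNAEvent("chr9", 0, 10_000, 1), genome)


def test_event_size_distribution_matches_theta(genome):
    config = cfg(genome, theta=1e6)
    rng = np.random.default_rng(0)
    lengths = [_sample_event(rng, config).length for _ in range(100_000)]
    assert np.mean(lengths) == pytest.approx(1e6, rel=0.05)


def test_gain_magnitude_matches_geometric_mean(genome):
    config = cfg(genome, gain_p=0.4, loss_fraction=0.0)
    rng = np.random.default_rng(0)
    deltas = [_sample_event(rng, config).delta for _ in range(100_000)]
    assert min(deltas) >= 1
    assert np.mean(deltas) == pytest.approx(1 / 0.4, rel=0.05)


def test_leaf_states_replay_from_root(small_tree):
    """Heritability: leaf CN = root CN + composed events on the root path."""
    matrix = small_tree.leaves_to_matrix()
    for row, leaf in zip(matrix.X, small_tree.leaves):
        path = [leaf]
        while small_tree.parent[path[-1]] >= 0:
            path.append(small_tree.parent[path[-1]])
        state = small_tree.root_state.copy()
        for node in reversed(path[:-1]):
            for ev in small_tree.edge_events[node]:
                state = apply_event(state, ev, small_tree.genome)
        assert np.array_equal(row, state)


def test_event_free_tree_is_all_diploid(genome):
    t = simulate_tree(cfg(genome, events_per_division=0.0, seed=3))
    assert np.all(t.leaves_to_matrix().X == 2)


def test_single_lineage_gain_marks_one_clade(genome):
    t = simulate_tree(cfg(genome, n_leaves=16, events_per_division=0.0, seed=3))
    # plant one whole-chromosome gain on an internal edge by hand
    internal = next(n for n in range(1, t.n_nodes) if not t.is_leaf(n))
    t.edge_events[internal] = [CNAEvent("chr1", 0, 100_000_000, 1)]
    matrix = t.leaves_to_matrix()
    clade = set(t.subtree_leaves(internal))
    for row, leaf in zip(matrix.X, t.leaves):
        assert np.all(row == (3 if leaf in clade else 2))


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def test_hom_grouping_partitions_leaves(small_tree):
    labels = scenario_hom(small_tree, k=5)
    values, counts = np.unique(labels, return_counts=True)
    assert len(values) == 5
    assert counts.sum() == small_tree.n_leaves
    assert np.all(counts >= 1)


def test_hom_k2_is_the_root_split(small_tree):
    labels = scenario_hom(small_tree, k=2)
    left = set(small_tree.subtree_leaves(small_tree.children[0][0]))
    expected = np.array(["S1" if l in left else "S2"
                         for l in small_tree.leaves])
    assert np.array_equal(labels, expected)


def test_het_grouping_reproducible_and_balanced(small_tree):
    a = scenario_het(small_tree, k=5, seed=7)
    b = scenario_het(small_tree, k=5, seed=7)
    assert np.array_equal(a, b)
    _, counts = np.unique(a, return_counts=True)
    assert counts.sum() == small_tree.n_leaves
    # multinomial: every group within a loose band around n/k
    assert counts.max() < 4 * small_tree.n_leaves // 5


def test_hom_scores_above_het_on_same_tree(genome):
    wins = 0
    for seed in range(5):
        t = simulate_tree(cfg(genome, n_leaves=150, seed=seed))
        D = pairwise_distance(t.leaves_to_matrix())
        hom = shscore_from_distances(D, scenario_hom(t, 5))
        het = shscore_from_distances(D, scenario_het(t, 5, seed=seed))
        wins += hom > het
    assert wins >= 4


def test_metastasis_scenario(genome):
    config = cfg(genome, n_leaves=50)
    prim, met, details = scenario_metastasis(
        config, seed_fraction=0.25, n_leaves_each=50, seed=9,
        return_details=True)
    assert prim.n_cells == 50 and met.n_cells == 50
    assert set(prim.sample_labels) == {"primary"}
    assert set(met.sample_labels) == {"metastasis"}
    seed_state = details["primary_tree"].node_state(details["seed_node"])
    assert np.array_equal(details["met_tree"].root_state, seed_state)


def test_metastasis_seed_depth_ordering(genome):
    config = cfg(genome, n_leaves=80)
    depths = {}
    for frac in (0.25, 0.75):
        _, _, details = scenario_metastasis(
            config, seed_fraction=frac, n_leaves_each=80, seed=4,
            return_details=True)
        depths[frac] = details["primary_tree"].depth(details["seed_node"])
    assert depths[0.25] <= depths[0.75]


def test_var_scenario(genome):
    a, b, theta, gain_p = scenario_var(seed=3, n_leaves=100, genome=genome)
    assert a.n_cells + b.n_cells == 100
    assert 500 <= theta <= 5_000_000
    assert 0.1 <= gain_p <= 0.9
    a2, b2, theta2, _ = scenario_var(seed=3, n_leaves=100, genome=genome)
    assert theta2 == theta
    assert np.array_equal(a.X, a2.X) and np.array_equal(b.X, b2.X)


def test_subtree_samples_and_iqr_filter(genome):
    t = simulate_tree(cfg(genome, n_leaves=400, seed=2))
    unfiltered = subtree_samples(t, 20, iqr_filter=False)
    assert len(unfiltered) == 20
    counts = np.array([m.n_cells for m, _ in unfiltered])
    assert counts.sum() == 400
    filtered = subtree_samples(t, 20, iqr_filter=True)
    q1, q3 = np.percentile(counts, [25, 75])
    for m, _ in filtered:
        assert q1 <= m.n_cells <= q3


# ---------------------------------------------------------------------------
# MRCA distances
# ---------------------------------------------------------------------------

def test_mrca_distance_basic(small_tree):
    c1, c2 = small_tree.children[0]
    assert mrca_distance(small_tree, c1, c2) == 2  # siblings
    assert mrca_distance(small_tree, c1, c1) == 0
    assert mrca_distance(small_tree, 0, c1) == 1
    with pytest.raises(SimulationError):
        mrca_distance(small_tree, 0, 10**6)


def test_mrca_distance_matches_bfs_oracle(small_tree, rng):
    nx = pytest.importorskip("networkx")
    G = nx.Graph()
    for node in range(1, small_tree.n_nodes):
        G.add_edge(node, small_tree.parent[node])
    for _ in range(30):
        a, b = rng.integers(0, small_tree.n_nodes, size=2)
        assert mrca_distance(small_tree, int(a), int(b)) == \
            nx.shortest_path_length(G, int(a), int(b))
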
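import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from mvfeeg.network import (
    ConnectivityGraph,
    SPARSITY_GRID,
    compute_pli,
    edge_count,
    metric_sweep,
    threshold_by_sparsity,
    weighted_clustering,
    weighted_shortest_path_length,
)
from mvfeeg.studies import (
    _phase_epochs,
    oracle_shortest_path_length,
    oracle_weighted_clustering,
    random_graph,
)


def _graph(w):
    return ConnectivityGraph(labels=tuple(f"n{i}" for i in range(w.shape[0])), weights=w)


# --- PLI -------------------------------------------------------------------

def test_pli_constant_lag_is_one():
    g = compute_pli(_phase_epochs("constant_lag", 10, seed=0), band=(8.0, 26.0))
    assert g.weights[0, 1] == 1.0


def test_pli_zero_lag_is_zero():
    g = compute_pli(_phase_epochs("zero_lag", 10, seed=0), band=(8.0, 26.0))
    assert g.weights[0, 1] == 0.0


def test_pli_invariant_to_amplitude_scaling_and_symmetric():
    ep = _phase_epochs("independent", 20, seed=1)
    g1 = compute_pli(ep, band=(8.0, 26.0))
    ep.data[:, 0, :] *= 7.5  # rescale one channel
    g2 = compute_pli(ep, band=(8.0, 26.0))
    assert g1.weights[0, 1] == pytest.approx(g2.weights[0, 1], rel=1e-9)
    assert np.array_equal(g1.weights, g1.weights.T)
    assert g1.weights[0, 0] == 0.0


def test_pli_needs_two_channels_and_enough_samples():
    ep = _phase_epochs("independent", 5, seed=2)
    short = ep.subset(np.ones(5, bool))
    short.analysis_start = None
    short.data = short.data[:, :, :100]
    short.times = short.times[:100]
    with pytest.raises(ValueError):
        compute_pli(short, band=(8.0, 26.0))


# --- thresholding ----------------------------------------------------------

def test_threshold_keeps_k_largest_edges():
    rng = np.random.default_rng(3)
    w = np.triu(rng.uniform(0.1, 1, (5, 5)), 1)
    w = w + w.T
    g = threshold_by_sparsity(_graph(w), 0.2)  # 10 possible -> 2 retained
    assert g.n_edges == 2
    kept = np.sort(g.weights[np.triu_indices(5, 1)])[-2:]
    largest = np.sort(w[np.triu_indices(5, 1)])[-2:]
    assert np.array_equal(kept, largest)


def test_threshold_sparsity_one_is_identity():
    g0 = random_graph(np.random.default_rng(4), 8, density=1.0)
    g1 = threshold_by_sparsity(g0, 1.0)
    assert np.array_equal(g0.weights, g1.weights)


def test_threshold_edge_cases():
    assert edge_count(32, 0.1) == 50  # round(0.1 * 496)
    with pytest.raises(ValueError):
        threshold_by_sparsity(random_graph(np.random.default_rng(5), 8), 0.001)
    with pytest.raises(ValueError):
        threshold_by_sparsity(random_graph(np.random.default_rng(5), 8), 1.5)


@given(hst.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_threshold_edge_sets_are_nested(seed):
    g = random_graph(np.random.default_rng(seed), 12, density=0.9)
    prev = None
    for s in SPARSITY_GRID:
        edges = set(map(tuple, np.argwhere(threshold_by_sparsity(g, s).weights > 0)))
        if prev is not None:
            assert prev <= edges
        prev = edges


# --- metrics ---------------------------------------------------------------

def test_complete_unit_graph_metrics():
    w = np.ones((8, 8)) - np.eye(8)
    g = _graph(w)
    assert weighted_clustering(g) == pytest.approx(1.0)
    wspl = weighted_shortest_path_length(g)
    assert wspl.value == pytest.approx(1.0)
    assert not wspl.disconnected


def test_uniform_weight_clustering_with_and_without_normalization():
    w = 0.4 * (np.ones((6, 6)) - np.eye(6))
    g = _graph(w)
    assert weighted_clustering(g, normalize=True) == pytest.approx(1.0)
    assert weighted_clustering(g, normalize=False) == pytest.approx(0.4)


def test_three_node_path_wspl():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    assert weighted_shortest_path_length(_graph(w)).value == pytest.approx(4.0 / 3.0)


def test_disconnected_pairs_flagged_and_excluded():
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    w[2, 3] = w[3, 2] = 0.5
    res = weighted_shortest_path_length(_graph(w))
    assert res.disconnected
    assert res.value == pytest.approx((1.0 + 2.0) / 2.0)  # mean over connected pairs


def test_metrics_match_bruteforce_oracles_on_random_graphs():
    rng = np.random.default_rng(6)
    for _ in range(20):
        g = random_graph(rng, 8)
        if g.n_edges == 0:
            continue
        assert weighted_clustering(g) == pytest.approx(
            oracle_weighted_clustering(g.weights), rel=1e-10)
        ov, odisc = oracle_shortest_path_length(g.weights)
        res = weighted_shortest_path_length(g)
        assert res.value == pytest.approx(ov, rel=1e-10)
        assert res.disconnected == odisc


def test_clustering_matches_networkx_onnela():
    # independent cross-check: networkx implements the same geometric-mean form
    g = random_graph(np.random.default_rng(7), 10, density=0.7)
    G = nx.from_numpy_array(g.weights / g.weights.max())
    expected = np.mean(list(nx.clustering(G, weight="weight").values()))
    assert weighted_clustering(g) == pytest.approx(expected, rel=1e-10)


def test_wspl_matches_networkx_dijkstra():
    g = random_graph(np.random.default_rng(8), 10, density=0.9)
    G = nx.Graph()
    G.add_nodes_from(range(10))
    for i, j in zip(*np.triu_indices(10, 1)):
        if g.weights[i, j] > 0:
            G.add_edge(int(i), int(j), length=1.0 / g.weights[i, j])
    d = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
    vals = [d[i][j] for i in range(10) for j in range(10) if i != j and j in d[i]]
    assert weighted_shortest_path_length(g).value == pytest.approx(np.mean(vals), rel=1e-10)


@given(hst.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_metrics_invariant_under_node_relabeling(seed):
    rng = np.random.default_rng(seed)
    g = random_graph(rng, 8, density=0.8)
    if g.n_edges == 0:
        return
    perm = rng.permutation(8)
    gp = _graph(g.weights[np.ix_(perm, perm)])
    assert weighted_clustering(gp) == pytest.approx(weighted_clustering(g), rel=1e-12)
    assert weighted_shortest_path_length(gp).value == pytest.approx(
        weighted_shortest_path_length(g).value, rel=1e-12)


def test_binary_graph_reduces_to_unweighted_definitions():
    rng = np.random.default_rng(9)
    w = (np.triu(rng.random((9, 9)), 1) < 0.5).astype(float)
    w = np.triu(w, 1)
    w = w + w.T
    g = _graph(w)
    G = nx.from_numpy_array(w)
    assert weighted_clustering(g) == pytest.approx(nx.average_clustering(G), rel=1e-12)
    # with unit weights, lengths are 1 -> hop counts
    d = dict(nx.all_pairs_shortest_path_length(G))
    vals = [d[i][j] for i in range(9) for j in range(9) if i != j and j in d[i]]
    assert weighted_shortest_path_length(g).value == pytest.approx(np.mean(vals))


def test_empty_graph_errors():
    g = _graph(np.zeros((5, 5)))
    with pytest.raises(ValueError):
        weighted_clustering(g)
    with pytest.raises(ValueError):
        weighted_shortest_path_length(g)


def test_metric_sweep_grid_and_monotonicity():
    g = random_graph(np.random.default_rng(10), 32, density=1.0)
    sweep = metric_sweep(g)
    assert len(sweep) == 6
    assert np.allclose(sweep["sparsity"], SPARSITY_GRID)
    # adding edges cannot lengthen shortest paths
    assert (np.diff(sweep["wspl"]) <= 1e-12).all()


def test_pli_uncoupled_noise_stays_low():
    g = compute_pli(_phase_epochs("independent", 60, seed=11), band=(8.0, 26.0))
    assert g.weights[0, 1] < 0.15
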
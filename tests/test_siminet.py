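"""Spatial graph-edit similarity: anchors, costs, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_adjacency
from oracles import reference_similarity
from scdnet.siminet import (
    SpatialGraph,
    edge_distance,
    graph_from_adjacency,
    node_edit_costs,
    similarity_index,
)


def square_graph(weights=None, offset=0.0):
    """4 nodes on a unit square with optional edges."""
    nodes = {
        "a": (0.0 + offset, 0.0, 0.0),
        "b": (1.0 + offset, 0.0, 0.0),
        "c": (1.0 + offset, 1.0, 0.0),
        "d": (0.0 + offset, 1.0, 0.0),
    }
    return SpatialGraph(nodes=nodes, edges=dict(weights or {}))


def test_identical_node_sets_cost_zero():
    g = square_graph({("a", "b"): 0.5})
    cost, corr = node_edit_costs(g, g)
    assert cost == 0.0
    assert corr.n_common == 4
    assert corr.n_substituted == corr.n_inserted == corr.n_deleted == 0


def test_extra_node_costs_one_insertion():
    g1 = square_graph()
    nodes2 = dict(g1.nodes) | {"e": np.array([0.5, 0.5, 0.0])}
    g2 = SpatialGraph(nodes=nodes2, edges={})
    cost, corr = node_edit_costs(g1, g2, c_ins=1.0)
    assert cost == pytest.approx(1.0)
    assert corr.n_inserted == 1 and corr.n_deleted == 0


def test_substitution_chosen_when_cheaper():
    """Two unmatched nodes at normalized distance 0.3 vs c_ins = 1."""
    # 4-node instance: three exact matches plus one displaced node whose
    # normalized displacement is 0.3 of the configuration diameter
    nodes1 = {"a": (0, 0, 0), "b": (10, 0, 0), "c": (0, 10, 0), "p": (10, 10, 0)}
    diam = np.sqrt(200.0)
    shift = 0.3 * diam
    nodes2 = {"a": (0, 0, 0), "b": (10, 0, 0), "c": (0, 10, 0),
              "q": (10 + shift, 10, 0)}
    g1 = SpatialGraph(nodes=nodes1, edges={})
    g2 = SpatialGraph(nodes=nodes2, edges={})
    cost, corr = node_edit_costs(g1, g2, c_ins=1.0, diameter=diam)
    assert corr.n_common == 3
    assert corr.n_substituted == 1
    assert cost == pytest.approx(0.3, abs=1e-9)
    # exhaustive check on this instance: delete+insert would cost 2.0
    assert cost < 2.0


def test_edge_distance_hand_cases():
    g1 = square_graph({("a", "b"): 0.8, ("c", "d"): 0.4})
    g2 = square_graph({("a", "b"): 0.5, ("c", "d"): 0.4})
    assert edge_distance(g1, g1) == 0.0
    assert edge_distance(g1, g2) == pytest.approx(0.3)

    rng = np.random.default_rng(5)
    pairs = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
    w1 = {p: float(rng.uniform(0, 1)) for p in pairs}
    w2 = {p: float(rng.uniform(0, 1)) for p in pairs[:4]}
    expected = sum(abs(w1[p] - w2.get(p, 0.0)) for p in pairs)
    assert edge_distance(square_graph(w1), square_graph(w2)) == pytest.approx(expected)


def test_identity_index_is_exactly_one():
    g = square_graph({("a", "b"): 0.8, ("b", "c"): 0.3})
    res = similarity_index(g, g)
    assert res.index == 1.0
    assert res.node_cost == 0.0 and res.edge_cost == 0.0


def test_disjoint_maximally_separated_graphs_score_zero():
    """No common nodes at maximal separation, disjoint edges -> index 0."""
    g1 = SpatialGraph(
        nodes={"a1": (0, 0, 0), "a2": (0, 0, 0)}, edges={("a1", "a2"): 0.9}
    )
    g2 = SpatialGraph(
        nodes={"b1": (100, 0, 0), "b2": (100, 0, 0)}, edges={("b1", "b2"): 0.7}
    )
    res = similarity_index(g1, g2)
    assert res.index == 0.0
    assert res.n_common == 0 and res.n_substituted == 0


def test_empty_pair_rejected():
    g = SpatialGraph(nodes={}, edges={})
    with pytest.raises(ValueError):
        similarity_index(g, g)


def test_single_edge_perturbation_strictly_decreasing_and_matches_reference():
    base_edges = {("a", "b"): 0.9, ("b", "c"): 0.9, ("c", "d"): 0.9}
    g1 = square_graph(base_edges)
    prev = 1.1
    for delta in np.arange(0.1, 0.95, 0.1):
        edges2 = dict(base_edges)
        edges2[("a", "b")] = round(0.9 - delta, 10)
        g2 = square_graph(edges2)
        res = similarity_index(g1, g2)
        ref = reference_similarity(
            {k: v for k, v in g1.nodes.items()}, g1.edges,
            {k: v for k, v in g2.nodes.items()}, g2.edges,
        )
        assert res.index == pytest.approx(ref, abs=1e-12)
        assert res.index < prev
        prev = res.index


def test_symmetry_of_index(rng):
    for _ in range(20):
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 6))
        nodes1 = {f"x{i}": rng.uniform(-10, 10, 3) for i in range(n1)}
        nodes2 = {f"y{i}": rng.uniform(-10, 10, 3) for i in range(n2)}
        ids1, ids2 = list(nodes1), list(nodes2)
        edges1 = {
            (a, b): float(rng.uniform(0, 1))
            for a in ids1 for b in ids1 if a < b and rng.random() < 0.5
        }
        edges2 = {
            (a, b): float(rng.uniform(0, 1))
            for a in ids2 for b in ids2 if a < b and rng.random() < 0.5
        }
        g1 = SpatialGraph(nodes=nodes1, edges=edges1)
        g2 = SpatialGraph(nodes=nodes2, edges=edges2)
        assert similarity_index(g1, g2).index == pytest.approx(
            similarity_index(g2, g1).index, abs=1e-12
        )


@settings(max_examples=100, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    alpha=st.floats(0.0, 1.0),
)
def test_index_bounded_for_random_graphs(seed, alpha):
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(1, 7, size=2)
    nodes1 = {f"x{i}": rng.uniform(-50, 50, 3) for i in range(n1)}
    nodes2 = {f"y{i}": rng.uniform(-50, 50, 3) for i in range(n2)}
    def med(nodes):
        ids = list(nodes)
        return {
            (a, b): float(rng.uniform(0, 1))
            for a in ids for b in ids if a < b and rng.random() < 0.4
        }
    g1 = SpatialGraph(nodes=nodes1, edges=med(nodes1))
    g2 = SpatialGraph(nodes=nodes2, edges=med(nodes2))
    res = similarity_index(g1, g2, alpha=alpha)
    assert 0.0 <= res.index <= 1.0
    assert res.node_cost >= 0 and res.edge_cost >= 0


def test_monotone_under_nested_perturbations(rng):
    """index(g, g_k) is non-increasing when perturbation sets are nested."""
    base_edges = {("a", "b"): 0.8, ("a", "c"): 0.8, ("b", "d"): 0.8, ("c", "d"): 0.8}
    g1 = square_graph(base_edges)
    edges = dict(base_edges)
    last = 1.0 + 1e-12
    for victim in list(base_edges):
        edges[victim] = 0.05  # each step extends the previous perturbation
        g2 = square_graph(edges)
        idx = similarity_index(g1, g2).index
        assert idx <= last + 1e-12
        last = idx


def test_graph_from_adjacency_threshold_and_presence(atlas, rng):
    mat = make_adjacency(rng, n=58, density=0.5, roi_order=atlas.roi_ids)
    g = graph_from_adjacency(mat, atlas, threshold_prop=0.2)
    n_off = 58 * 57 // 2
    assert len(g.edges) <= int(round(0.2 * n_off)) + 1
    # every present node has degree > 0 by construction
    endpoints = {v for pair in g.edges for v in pair}
    assert set(g.nodes) == endpoints
    kept = sorted(g.edges.values())
    dropped = [
        mat.values[i, j]
        for i in range(58) for j in range(i + 1, 58)
        if (atlas.roi_ids[i], atlas.roi_ids[j]) not in g.edges
        and mat.values[i, j] > 0
    ]
    if kept and dropped:
        assert min(kept) >= max(dropped) - 1e-12
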
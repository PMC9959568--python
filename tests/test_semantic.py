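"""Semantic map: MST vs enumeration oracle, hubs, central node, export."""

import itertools

import networkx as nx
import numpy as np
import pytest

from olfmap.errors import DataError, ParameterError
from olfmap.semantic import (
    MapEdge,
    SemanticMap,
    build_semantic_map,
    central_node,
    enumerate_spanning_trees,
    export_map,
    find_hubs,
    minimum_spanning_tree_edges,
    read_map_tsv,
    tree_energy,
)


def _random_distance_matrix(rng, n):
    d = rng.uniform(0.05, 1.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


def _map_from_strengths(names, s):
    return build_semantic_map(names, np.asarray(s, dtype=float))


def _path_map(labels, strength=0.5):
    edges = [
        MapEdge(a, b, strength, 1 - strength)
        for a, b in zip(labels, labels[1:])
    ]
    return SemanticMap(nodes=list(labels), edges=edges)


def _star_map(center, leaves, strength=0.5):
    edges = [MapEdge(center, l, strength, 1 - strength) for l in leaves]
    return SemanticMap(nodes=[center] + list(leaves), edges=edges)


# ---------------------------------------------------------------------------
# Spanning trees
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 16), (5, 125)])
def test_cayley_tree_counts(n, count):
    out = enumerate_spanning_trees(n)
    assert out["count"] == count == n ** max(n - 2, 0)
    # all trees distinct and genuinely spanning
    seen = {tuple(t) for t in out["trees"]}
    assert len(seen) == count
    for t in out["trees"]:
        g = nx.Graph(t)
        assert g.number_of_nodes() == n and nx.is_tree(g)


def test_enumeration_range_validated():
    with pytest.raises(ParameterError):
        enumerate_spanning_trees(1)
    with pytest.raises(ParameterError):
        enumerate_spanning_trees(9)


def test_triangle_mst_picks_two_smallest():
    d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
    edges = minimum_spanning_tree_edges(["A", "B", "C"], d)
    assert sorted(edges) == [("A", "B"), ("A", "C")]


def test_two_node_mst():
    d = np.array([[0.0, 0.4], [0.4, 0.0]])
    assert minimum_spanning_tree_edges(["x", "y"], d) == [("x", "y")]


def test_mst_matches_enumeration_oracle():
    """MST total equals the minimum over all exhaustively enumerated
    spanning trees for n = 4..6 across 50 random matrices."""
    rng = np.random.default_rng(123)
    for trial in range(50):
        n = int(rng.integers(4, 7))
        d = _random_distance_matrix(rng, n)
        names = [f"n{i}" for i in range(n)]
        edges = minimum_spanning_tree_edges(names, d)
        total = sum(d[int(a[1:]), int(b[1:])] for a, b in edges)
        oracle = enumerate_spanning_trees(n, distances=d)
        assert total == pytest.approx(oracle["best_total"])


def test_mst_deterministic_under_ties():
    names = ["A", "B", "C", "D"]
    d = np.full((4, 4), 0.5)
    np.fill_diagonal(d, 0.0)
    edges = minimum_spanning_tree_edges(names, d)
    # all distances equal: lexicographic tie-break gives the A-star
    assert edges == [("A", "B"), ("A", "C"), ("A", "D")]


def test_mst_input_validation():
    with pytest.raises(ParameterError):
        minimum_spanning_tree_edges(["A"], np.zeros((1, 1)))
    bad = np.array([[0.0, np.inf], [np.inf, 0.0]])
    with pytest.raises(DataError):
        minimum_spanning_tree_edges(["A", "B"], bad)
    asym = np.array([[0.0, 0.2], [0.5, 0.0]])
    with pytest.raises(DataError):
        minimum_spanning_tree_edges(["A", "B"], asym)


# ---------------------------------------------------------------------------
# Hubs, central node, energy
# ---------------------------------------------------------------------------


def test_hubs_star_and_path():
    assert find_hubs(_star_map("hub", ["a", "b", "c", "d"])) == ["hub"]
    assert find_hubs(_path_map(["a", "b", "c", "d"])) == ["b", "c"]


def test_central_node_path_and_star():
    assert central_node(_path_map(["A", "B", "C", "D", "E"])) == "C"
    assert central_node(_star_map("S", ["a", "b", "c"])) == "S"


def test_central_node_tie_breaks():
    # even path: B and C survive pruning; C holds more incident strength
    edges = [
        MapEdge("A", "B", 0.2, 0.8),
        MapEdge("B", "C", 0.5, 0.5),
        MapEdge("C", "D", 0.9, 0.1),
    ]
    smap = SemanticMap(nodes=list("ABCD"), edges=edges)
    assert central_node(smap) == "C"
    # exact strength tie: lexicographically smaller label wins
    sym = _path_map(["D", "B", "C", "A"], strength=0.5)
    assert central_node(sym) == "B"


def test_central_node_matches_classical_tree_center():
    """Leaf pruning lands on the eccentricity-minimizing center of random
    trees (choosing within nx.center when two nodes remain)."""
    rng = np.random.default_rng(9)
    for trial in range(30):
        n = int(rng.integers(3, 12))
        t = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
        edges = [
            MapEdge(str(a), str(b), float(rng.uniform(0.1, 1.0)), 0.5)
            for a, b in t.edges
        ]
        smap = SemanticMap(nodes=[str(v) for v in t.nodes], edges=edges)
        center = {str(v) for v in nx.center(t)}
        assert central_node(smap) in center


def test_tree_energy_and_totals():
    single = SemanticMap(nodes=["a", "b"], edges=[MapEdge("a", "b", 0.9, 0.1)])
    assert tree_energy(single) == pytest.approx(0.9)
    n = 5
    allmax = _star_map("h", [f"l{i}" for i in range(n - 1)], strength=1.0)
    assert tree_energy(allmax) == pytest.approx(n - 1)


def test_build_semantic_map_structure():
    rng = np.random.default_rng(4)
    n = 6
    s = rng.uniform(0, 0.95, size=(n, n))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 0.0)
    names = [f"v{i}" for i in range(n)]
    smap = _map_from_strengths(names, s)
    smap.validate()
    assert len(smap.edges) == n - 1
    assert smap.energy == pytest.approx(sum(e.strength for e in smap.edges))
    assert smap.total_distance == pytest.approx(
        sum(e.distance for e in smap.edges)
    )
    assert smap.central_node in smap.nodes
    assert set(smap.hubs) <= set(smap.nodes)


def test_planted_star_variable_is_recovered_as_hub():
    """A driver variable co-activating with several satellites (noisy over
    seeds) is the map hub in at least 80% of runs."""
    from olfmap.autocm import BinaryDataset, connection_strengths, train_autocm

    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        n = 240
        hub = (rng.random(n) < 0.75).astype(float)
        cols = [hub]
        # satellites follow the hub in disjoint blocks, plus flip noise
        for s_ix in range(4):
            sat = hub.copy()
            block = slice(s_ix * (n // 4), (s_ix + 1) * (n // 4))
            flip = rng.random(n) < 0.35
            sat[block] = np.where(flip[block], 1 - sat[block], sat[block])
            mask = np.ones(n, bool)
            mask[block] = False
            sat[mask] = np.where(rng.random(mask.sum()) < 0.5, 0.0, sat[mask])
            cols.append(sat)
        ds = BinaryDataset(["hub"] + [f"s{i}" for i in range(4)],
                           np.column_stack(cols))
        smap = _map_from_strengths(ds.variable_names,
                                   connection_strengths(train_autocm(ds)))
        hits += "hub" in smap.hubs
    assert hits >= 0.8 * n_seeds


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def test_edge_list_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    s = rng.integers(0, 10000, size=(5, 5)) / 10000  # 4 d.p. exact
    s = (s + s.T) / 2
    s = np.round(s, 4)
    np.fill_diagonal(s, 0.0)
    smap = _map_from_strengths([f"v{i}" for i in range(5)], s)
    path = export_map(smap, tmp_path / "edges.tsv", fmt="tsv")
    back = read_map_tsv(path)
    assert back.nodes == sorted(smap.nodes)
    assert {(e.a, e.b) for e in back.edges} == {(e.a, e.b) for e in smap.edges}
    for e1, e2 in zip(
        sorted(back.edges, key=lambda e: (e.a, e.b)),
        sorted(smap.edges, key=lambda e: (e.a, e.b)),
    ):
        assert e1.strength == pytest.approx(e2.strength, abs=5e-5)
        assert e1.distance == pytest.approx(e2.distance)
    assert back.hubs == smap.hubs
    assert back.central_node == smap.central_node
    assert back.energy == pytest.approx(smap.energy)


def test_two_node_map_exports_single_line(tmp_path):
    smap = SemanticMap(nodes=["a", "b"], edges=[MapEdge("a", "b", 0.9, 0.1)],
                       hubs=["a", "b"], central_node="a", energy=0.9,
                       total_distance=0.1)
    path = export_map(smap, tmp_path / "m.tsv", fmt="tsv")
    data_lines = [
        l for l in path.read_text().splitlines()
        if l and not l.startswith("#") and not l.startswith("node_a")
    ]
    assert len(data_lines) == 1


def test_graphml_and_dot_exports(tmp_path):
    smap = _star_map("center", ["a", "b", "c"], strength=0.8)
    smap.hubs = find_hubs(smap)
    smap.central_node = central_node(smap)
    g_path = export_map(smap, tmp_path / "m.graphml", fmt="graphml")
    g = nx.read_graphml(g_path)
    assert g.number_of_edges() == 3
    assert g.nodes["center"]["hub"] is True
    d_path = export_map(smap, tmp_path / "m.dot", fmt="dot")
    text = d_path.read_text()
    assert '"center" -- ' in text and "central=true" in text
    with pytest.raises(ParameterError):
        export_map(smap, tmp_path / "m.x", fmt="svg")
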
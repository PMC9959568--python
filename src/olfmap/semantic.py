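"""Semantic connectivity map: MST filter, hubs, central node, energy, export.

The map is the minimum spanning tree (MST) of the Auto-CM distance matrix:
the unique loop-free skeleton connecting all variables with the smallest
total distance, i.e. keeping only the associations necessary to hold the
system together. On top of the tree this module extracts

* hubs — the nodes of maximal degree;
* the central node — the node left standing when leaves are pruned
  bottom-up, recursively (the classical tree center); an even-diameter
  tree leaves two candidates and the tie goes to the one with the larger
  sum of incident edge strengths, then to the lexicographically smaller
  label;
* the tree energy — the sum of edge connection strengths, reported
  alongside the total distance the MST minimizes.

Determinism: candidate edges are inserted in lexicographic label order, so
Kruskal's stable sort breaks equal-distance ties lexicographically and the
map is identical across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import DataError, ParameterError

EXPORT_FORMATS = ("tsv", "graphml", "dot")


@dataclass(frozen=True)
class MapEdge:
    a: str
    b: str
    strength: float
    distance: float


@dataclass
class SemanticMap:
    """A spanning tree over the map variables with its derived features."""

    nodes: list[str]
    edges: list[MapEdge]
    hubs: list[str] = field(default_factory=list)
    central_node: str = ""
    energy: float = 0.0
    total_distance: float = 0.0

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.a, e.b, strength=e.strength, distance=e.distance)
        return g

    def validate(self) -> None:
        g = self.to_graph()
        if len(self.edges) != len(self.nodes) - 1 or not nx.is_connected(g):
            raise DataError("semantic map is not a spanning tree")


def _check_distance_matrix(dist: np.ndarray, n: int) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (n, n):
        raise ParameterError(f"distance matrix shape {dist.shape} != ({n}, {n})")
    if not np.isfinite(dist).all():
        raise DataError("distance matrix has non-finite entries")
    if (dist < 0).any():
        raise DataError("distances must be non-negative")
    if not np.allclose(dist, dist.T):
        raise DataError("distance matrix must be symmetric")
    return dist


def minimum_spanning_tree_edges(
    names: list[str], dist: np.ndarray
) -> list[tuple[str, str]]:
    """MST edge list by Kruskal with lexicographic tie-breaking."""
    if len(names) < 2:
        raise ParameterError("need at least 2 nodes for a spanning tree")
    dist = _check_distance_matrix(dist, len(names))
    order = sorted(range(len(names)), key=lambda i: names[i])
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, j in itertools.combinations(order, 2):
        a, b = sorted((names[i], names[j]))
        g.add_edge(a, b, weight=float(dist[i, j]))
    mst = nx.minimum_spanning_edges(g, algorithm="kruskal", data=False)
    return [tuple(sorted(e)) for e in mst]


def build_semantic_map(
    names: list[str],
    strengths: np.ndarray,
    age_note: str | None = None,
) -> SemanticMap:
    """Assemble the full semantic map from a strength matrix.

    Distances are ``1 - s``; the MST, hubs, central node, energy and total
    distance are all computed here.
    """
    strengths = np.asarray(strengths, dtype=float)
    dist = 1.0 - strengths
    np.fill_diagonal(dist, 0.0)
    idx = {name: i for i, name in enumerate(names)}
    edges = []
    for a, b in minimum_spanning_tree_edges(list(names), dist):
        i, j = idx[a], idx[b]
        edges.append(
            MapEdge(a, b, strength=float(strengths[i, j]), distance=float(dist[i, j]))
        )
    smap = SemanticMap(
        nodes=list(names),
        edges=edges,
        energy=float(sum(e.strength for e in edges)),
        total_distance=float(sum(e.distance for e in edges)),
    )
    smap.hubs = find_hubs(smap)
    smap.central_node = central_node(smap)
    return smap


def enumerate_spanning_trees(
    n: int, distances: np.ndarray | None = None
) -> dict:
    """Enumerate all labelled spanning trees of the complete graph K_n.

    Uses Pruefer sequences, so the count is Cayley's ``n^(n-2)``; capped at
    n = 8 (262144 trees). With a distance matrix, also returns the
    minimum-total tree and its total. Nodes are integers 0..n-1.
    """
    if not (2 <= n <= 8):
        raise ParameterError(f"n must be in [2, 8], got {n}")
    trees = []
    for seq in itertools.product(range(n), repeat=n - 2):
        t = nx.from_prufer_sequence(list(seq))
        trees.append(sorted(tuple(sorted(e)) for e in t.edges))
    out = {"count": len(trees), "trees": trees}
    if distances is not None:
        distances = _check_distance_matrix(distances, n)
        totals = [sum(distances[i, j] for i, j in t) for t in trees]
        best = int(np.argmin(totals))
        out["best_tree"] = trees[best]
        out["best_total"] = float(totals[best])
    return out


def find_hubs(smap: SemanticMap) -> list[str]:
    """All nodes attaining the maximal degree of the tree."""
    g = smap.to_graph()
    degrees = dict(g.degree())
    top = max(degrees.values())
    return sorted(n for n, d in degrees.items() if d == top)


def central_node(smap: SemanticMap) -> str:
    """Recursive bottom-up leaf pruning; the surviving node is central.

    When pruning leaves two nodes (even-diameter trees), the tie goes to
    the larger incident-strength sum in the map, then to the smaller label.
    """
    g = smap.to_graph()
    if g.number_of_nodes() == 0:
        raise ParameterError("empty map has no central node")
    if g.number_of_nodes() == 1:
        return next(iter(g.nodes))
    strength_sum = {n: 0.0 for n in smap.nodes}
    for e in smap.edges:
        strength_sum[e.a] += e.strength
        strength_sum[e.b] += e.strength
    while g.number_of_nodes() > 2:
        leaves = [n for n in g.nodes if g.degree(n) <= 1]
        g.remove_nodes_from(leaves)
    survivors = sorted(g.nodes)
    if len(survivors) == 1:
        return survivors[0]
    return min(survivors, key=lambda n: (-strength_sum[n], n))


def tree_energy(smap: SemanticMap) -> float:
    """Sum of edge connection strengths over the tree."""
    return float(sum(e.strength for e in smap.edges))


def export_map(smap: SemanticMap, path, fmt: str = "tsv") -> Path:
    """Serialize the map; formats: edge-list TSV, GraphML, DOT.

    The TSV carries strength to 4 decimal places and distance at full
    precision, plus hub/central annotations in comment lines; GraphML and
    DOT carry strength and distance as edge attributes and flag hubs and
    the central node as node attributes.
    """
    path = Path(path)
    if fmt not in EXPORT_FORMATS:
        raise ParameterError(f"unknown export format {fmt!r}; use {EXPORT_FORMATS}")
    if fmt == "tsv":
        lines = [
            f"# central_node\t{smap.central_node}",
            "# hubs\t" + ",".join(smap.hubs),
            f"# energy\t{smap.energy!r}",
            f"# total_distance\t{smap.total_distance!r}",
            "node_a\tnode_b\tstrength\tdistance",
        ]
        for e in sorted(smap.edges, key=lambda e: (e.a, e.b)):
            lines.append(f"{e.a}\t{e.b}\t{e.strength:.4f}\t{e.distance!r}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "graphml":
        g = smap.to_graph()
        for n in g.nodes:
            g.nodes[n]["hub"] = n in smap.hubs
            g.nodes[n]["central"] = n == smap.central_node
        nx.write_graphml(g, path)
    else:  # dot
        lines = ["graph semantic_map {"]
        for n in sorted(smap.nodes):
            attrs = []
            if n in smap.hubs:
                attrs.append("hub=true")
            if n == smap.central_node:
                attrs.append('color=red central=true')
            attr_s = f" [{' '.join(attrs)}]" if attrs else ""
            lines.append(f'    "{n}"{attr_s};')
        for e in sorted(smap.edges, key=lambda e: (e.a, e.b)):
            lines.append(
                f'    "{e.a}" -- "{e.b}" '
                f'[label="{e.strength:.2f}" strength={e.strength:.4f} '
                f"distance={e.distance:.4f}];"
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    return path


def read_map_tsv(path) -> SemanticMap:
    """Reconstruct a SemanticMap from its edge-list TSV export."""
    meta: dict[str, str] = {}
    edges: list[MapEdge] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("\t")
            meta[key.strip()] = val.strip()
            continue
        if line.startswith("node_a\t"):
            continue
        a, b, s, d = line.split("\t")
        edges.append(MapEdge(a, b, strength=float(s), distance=float(d)))
    nodes = sorted({n for e in edges for n in (e.a, e.b)})
    smap = SemanticMap(
        nodes=nodes,
        edges=edges,
        hubs=[h for h in meta.get("hubs", "").split(",") if h],
        central_node=meta.get("central_node", ""),
        energy=float(meta.get("energy", "nan")),
        total_distance=float(meta.get("total_distance", "nan")),
    )
    return smap
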
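"""Enumerate the spanning trees of four points and find the shortest one.

Four labelled points admit 4^2 = 16 distinct spanning trees (Cayley's
formula); given pairwise distances, exactly one of them minimizes the
total length — the minimum spanning tree the semantic map is built on.
"""

import numpy as np

from olfmap import enumerate_spanning_trees, minimum_spanning_tree_edges

# symmetric distances between 4 points (0-1-2-3)
d = np.array(
    [
        [0.0, 1.0, 4.0, 3.0],
        [1.0, 0.0, 2.0, 5.0],
        [4.0, 2.0, 0.0, 3.0],
        [3.0, 5.0, 3.0, 0.0],
    ]
)

out = enumerate_spanning_trees(4, distances=d)
print(f"number of spanning trees on 4 labelled nodes: {out['count']}")
print(f"shortest tree: {out['best_tree']} with total {out['best_total']}")

edges = minimum_spanning_tree_edges(["A", "B", "C", "D"], d)
print(f"MST (Kruskal): {edges}")
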
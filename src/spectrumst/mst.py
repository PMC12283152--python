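"""Minimum-spanning-tree backbones and their topology metrics.

The backbone of a functional network is extracted by running Kruskal's
algorithm on inverted coupling weights (distance = 1/weight), so the
resulting minimum spanning tree keeps the N-1 strongest connections that
join all regions without cycles — formally a maximum spanning tree of the
similarity weights.  Because the MST always has exactly N-1 edges, trees
from different subjects or groups can be compared without an arbitrary
density threshold.

Global topology is summarized by the leaf fraction, the diameter and the
tree hierarchy; regional topology by per-node betweenness centrality.
Conventions (all give values on a [0,1]-type scale):

- leaf fraction   L / M          (M = N-1 edges; star = 1)
- diameter        d / M          (path = 1)
- betweenness     pairs through the node / ((N-1)(N-2)/2)  (star center = 1)
- tree hierarchy  L / (2 M BCmax), BCmax the maximum normalized
  betweenness; in (0, 0.5], star = 0.5, long path -> small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix
from .errors import ConsistencyError

__all__ = [
    "SpanningTree",
    "TreeMetrics",
    "invert_weights",
    "kruskal_mst",
    "mst_from_connectivity",
    "leaf_fraction",
    "diameter",
    "betweenness",
    "tree_hierarchy",
    "tree_metrics",
    "metrics_over_epochs",
]

DEFAULT_EPSILON = 1e-6


@dataclass
class SpanningTree:
    """A binary acyclic connected backbone: exactly N-1 unordered edges."""

    n_nodes: int
    edges: frozenset
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = self.n_nodes
        if n < 2:
            raise ConsistencyError("a spanning tree needs at least 2 nodes")
        edges = frozenset(
            (min(i, j), max(i, j)) for i, j in self.edges
        )
        if len(edges) != n - 1:
            raise ConsistencyError(
                f"a spanning tree on {n} nodes has {n - 1} edges, "
                f"got {len(edges)}"
            )
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j in edges:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ConsistencyError(f"invalid edge ({i}, {j})")
            ri, rj = find(i), find(j)
            if ri == rj:
                raise ConsistencyError("edges contain a cycle")
            parent[ri] = rj
        # n-1 successful unions on n nodes <=> connected and acyclic
        self.edges = edges
        if not self.roi_labels:
            self.roi_labels = [f"roi{i:03d}" for i in range(n)]
        if len(self.roi_labels) != n:
            raise ConsistencyError("label count must equal node count")

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def edge_label_pairs(self) -> frozenset:
        """Edges as unordered ROI-label pairs (comparison across orderings)."""
        lab = self.roi_labels
        return frozenset(frozenset((lab[i], lab[j])) for i, j in self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


@dataclass
class TreeMetrics:
    """Global and regional MST topology, possibly averaged over epochs."""

    leaf_fraction: float
    diameter_edges: float
    diameter_norm: float
    tree_hierarchy: float
    bc: np.ndarray
    roi_labels: list[str] = field(default_factory=list)


def invert_weights(c: ConnectivityMatrix,
                   epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Distance matrix d = 1/max(w, epsilon); strictly order-reversing on
    weights above the epsilon floor.  The diagonal is set to 0 and ignored
    downstream."""
    if epsilon <= 0:
        raise ConsistencyError("epsilon must be positive")
    d = 1.0 / np.maximum(c.weights, epsilon)
    np.fill_diagonal(d, 0.0)
    return d


def kruskal_mst(d: np.ndarray, roi_labels: list[str] | None = None
                ) -> SpanningTree:
    """Kruskal's algorithm on a symmetric distance matrix.

    Edges are ranked from the lowest to the highest distance; each edge is
    added unless it would close a cycle, until all nodes are connected.
    Ties are broken deterministically by (distance, i, j) with i < j, so
    repeated runs are reproducible even with equal weights.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ConsistencyError("distance matrix must be square")
    if n < 2:
        raise ConsistencyError("need at least 2 nodes")
    iu, ju = np.triu_indices(n, k=1)
    dist = d[iu, ju]
    if not np.all(np.isfinite(dist)):
        raise ConsistencyError("distances must be finite")
    order = np.lexsort((ju, iu, dist))
    iu, ju = iu[order], ju[order]

    parent = np.arange(n)

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:  # path compression
            parent[a], a = root, parent[a]
        return root

    edges = []
    for i, j in zip(iu.tolist(), ju.tolist()):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j))
            if len(edges) == n - 1:
                break
    assert len(edges) == n - 1, "input graph was not connected"
    return SpanningTree(n, frozenset(edges),
                        list(roi_labels) if roi_labels else [])


def mst_from_connectivity(c: ConnectivityMatrix,
                          epsilon: float = DEFAULT_EPSILON) -> SpanningTree:
    """Backbone of a connectivity matrix: invert weights, then Kruskal."""
    return kruskal_mst(invert_weights(c, epsilon), c.roi_labels)


# ---------------------------------------------------------------------------
# topology metrics


def _require(t: SpanningTree, n_min: int, metric: str) -> None:
    if t.n_nodes < n_min:
        raise ConsistencyError(f"{metric} needs at least {n_min} nodes")


def leaf_fraction(t: SpanningTree) -> float:
    """Number of degree-1 nodes divided by the number of edges M = N-1."""
    _require(t, 3, "leaf fraction")
    leaves = int(np.sum(t.degrees() == 1))
    return leaves / (t.n_nodes - 1)


def diameter(t: SpanningTree) -> tuple[int, float]:
    """Longest shortest path, in edges and normalized by M = N-1."""
    _require(t, 2, "diameter")
    g = t.to_networkx()
    ecc = nx.eccentricity(g)
    d = max(ecc.values())
    return d, d / (t.n_nodes - 1)


def betweenness(t: SpanningTree) -> np.ndarray:
    """Per-node betweenness centrality, normalized to [0, 1].

    For a tree this is the fraction of the (N-1)(N-2)/2 unordered pairs of
    other nodes whose unique path crosses the node.
    """
    _require(t, 3, "betweenness")
    bc = nx.betweenness_centrality(t.to_networkx(), normalized=True)
    return np.array([bc[i] for i in range(t.n_nodes)])


def tree_hierarchy(t: SpanningTree) -> float:
    """Th = L / (2 M BCmax): balances integration (many leaves) against
    overload of the most central node; 0.5 for a star, small for a path."""
    _require(t, 3, "tree hierarchy")
    leaves = int(np.sum(t.degrees() == 1))
    m = t.n_nodes - 1
    bc_max = float(betweenness(t).max())
    assert bc_max > 0.0, "BCmax cannot vanish for N >= 3"
    return leaves / (2.0 * m * bc_max)


def tree_metrics(t: SpanningTree) -> TreeMetrics:
    """All metrics of a single tree, with bounds asserted."""
    lf = leaf_fraction(t)
    d_edges, d_norm = diameter(t)
    bc = betweenness(t)
    th = tree_hierarchy(t)
    assert 0.0 < lf <= 1.0 and 0.0 < d_norm <= 1.0
    assert 0.0 < th <= 0.5 and bc.min() >= 0.0 and bc.max() <= 1.0
    return TreeMetrics(lf, float(d_edges), d_norm, th, bc,
                       list(t.roi_labels))


def metrics_over_epochs(trees: list[SpanningTree]) -> TreeMetrics:
    """Metrics computed per epoch tree, then arithmetically averaged."""
    if not trees:
        raise ConsistencyError("need at least one tree")
    first = trees[0]
    for t in trees[1:]:
        if t.n_nodes != first.n_nodes or t.roi_labels != first.roi_labels:
            raise ConsistencyError("trees have inconsistent node sets")
    per = [tree_metrics(t) for t in trees]
    return TreeMetrics(
        leaf_fraction=float(np.mean([m.leaf_fraction for m in per])),
        diameter_edges=float(np.mean([m.diameter_edges for m in per])),
        diameter_norm=float(np.mean([m.diameter_norm for m in per])),
        tree_hierarchy=float(np.mean([m.tree_hierarchy for m in per])),
        bc=np.mean([m.bc for m in per], axis=0),
        roi_labels=list(first.roi_labels),
    )
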
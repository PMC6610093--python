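"""Spanning trees of strongest connections and their topology metrics.

The tree of strongest functional connections is built with Kruskal's
algorithm run on descending PLI weight — equivalently, the minimum
spanning tree after the weight transform w -> 1 - w. Because the tree is
acyclic, every node pair is joined by a unique path, which makes the
classic metrics cheap and well-defined:

- leaf number L (degree-1 nodes) and leaf fraction L_f = L / m with
  m = N - 1 edges; L ranges from 2 (path) to m (star);
- diameter d in hops, bounded by d_max = m - L + 2;
- betweenness centrality BC(u), the fraction of node pairs whose path
  crosses u, normalized by (N-1)(N-2)/2 so a star hub scores exactly 1
  and every leaf scores 0;
- degree correlation R, Newman's edge-endpoint assortativity — negative
  values mean hubs attach to low-degree nodes (disassortative);
- regional BC, the mean BC over anterior and posterior electrode sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix
from .montage import ANTERIOR, CENTRAL, POSTERIOR


@dataclass
class SpanningTree:
    """An acyclic connected subgraph on the electrode set.

    ``edges`` holds (label_a, label_b, weight) triples; a valid tree on N
    nodes has exactly N - 1 of them.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if n < 2:
            raise ValueError("a spanning tree needs >= 2 nodes")
        if len(set(self.nodes)) != n:
            raise ValueError("duplicate node labels")
        if len(self.edges) != n - 1:
            raise ValueError(f"{len(self.edges)} edges for {n} nodes; need {n - 1}")
        g = self.to_networkx()
        if g.number_of_nodes() != n or not nx.is_connected(g):
            raise ValueError("edge set does not connect all nodes")
        # |E| = |V| - 1 and connected => acyclic

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b, _ in self.edges}


@dataclass
class RegionConfig:
    """Anterior/posterior electrode sets for regional centrality.

    The central strip is excluded from both regions so every node is
    unambiguously frontal or non-frontal.
    """

    anterior: frozenset[str] = field(default_factory=lambda: ANTERIOR)
    posterior: frozenset[str] = field(default_factory=lambda: POSTERIOR)
    excluded: frozenset[str] = field(default_factory=lambda: CENTRAL)

    def __post_init__(self) -> None:
        a, p, e = map(frozenset, (self.anterior, self.posterior, self.excluded))
        if a & p or a & e or p & e:
            raise ValueError("region sets must be disjoint")
        self.anterior, self.posterior, self.excluded = a, p, e


@dataclass
class MSTMetrics:
    """One subject-band record of global and regional tree metrics."""

    max_degree: float
    leaf_number: float
    leaf_fraction: float
    diameter: float
    diameter_norm: float  # d / m, for cross-study comparison
    bc_max: float
    bc_global: float
    degree_correlation: float
    bc_anterior: float
    bc_posterior: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class _UnionFind:
    def __init__(self, items):
        self._parent = {x: x for x in items}

    def find(self, x):
        while self._parent[x] != x:
            self._parent[x] = self._parent[self._parent[x]]
            x = self._parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self._parent[rb] = ra
        return True


def max_spanning_tree(mat: ConnectivityMatrix) -> SpanningTree:
    """Kruskal's algorithm on descending weight.

    Edges are sorted strongest first; an edge joins the tree unless it
    would close a loop. Equal weights are broken lexicographically on the
    (label_a, label_b) pair, so the tree is reproducible across runs and
    platforms. Zero-weight edges are admissible (an all-positive PLI
    matrix is complete, so connectivity is guaranteed; an adversarial
    matrix whose nonzero edges leave the graph disconnected is rejected).
    """
    n = mat.n
    if n < 2:
        raise ValueError("need >= 2 nodes to span")
    labels = mat.labels
    iu, ju = np.triu_indices(n, k=1)
    candidates = sorted(
        ((float(mat.values[i, j]), labels[i], labels[j]) for i, j in zip(iu, ju)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    uf = _UnionFind(labels)
    edges: list[tuple[str, str, float]] = []
    for w, a, b in candidates:
        if uf.union(a, b):
            edges.append((a, b, w))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        raise ValueError("graph is disconnected; no spanning tree exists")
    if any(w == 0 for _, _, w in edges):
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_edges_from((a, b) for w, a, b in candidates if w > 0)
        if not nx.is_connected(g):
            raise ValueError("nonzero-weight edges leave the graph disconnected")
    return SpanningTree(list(labels), edges)


def degree_metrics(tree: SpanningTree) -> tuple[dict[str, int], int]:
    """Per-node degrees and the maximal degree."""
    g = tree.to_networkx()
    degrees = dict(g.degree())
    return degrees, max(degrees.values())


def leaf_metrics(tree: SpanningTree) -> tuple[int, float]:
    """Leaf number L (degree-1 nodes) and leaf fraction L_f = L / (N-1)."""
    degrees, _ = degree_metrics(tree)
    leaves = sum(1 for d in degrees.values() if d == 1)
    return leaves, leaves / (tree.n - 1)


def diameter(tree: SpanningTree) -> int:
    """Largest inter-node distance in edge hops."""
    return nx.diameter(tree.to_networkx())


def betweenness(tree: SpanningTree) -> tuple[dict[str, float], float, float]:
    """Node betweenness centrality, its maximum, and its mean.

    Normalized by (N-1)(N-2)/2 node pairs, so BC(u) is the fraction of
    pairs whose unique tree path passes through u: star hub = 1, leaf = 0.
    The global value is the mean over all N nodes, leaves included.
    """
    bc = nx.betweenness_centrality(tree.to_networkx(), normalized=True)
    vals = np.array(list(bc.values()))
    return bc, float(vals.max()), float(vals.mean())


def degree_correlation(tree: SpanningTree) -> float:
    """Newman's degree assortativity over edge endpoints, in [-1, 1].

    NaN when endpoint degrees have zero variance (e.g. the 2-node tree),
    where the correlation is undefined.
    """
    deg = dict(tree.to_networkx().degree())
    # endpoint degree pairs in both orientations
    x = np.array([deg[a] for a, b, _ in tree.edges]
                 + [deg[b] for a, b, _ in tree.edges], dtype=float)
    y = np.array([deg[b] for a, b, _ in tree.edges]
                 + [deg[a] for a, b, _ in tree.edges], dtype=float)
    if np.ptp(x) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def regional_bc(tree: SpanningTree,
                regions: RegionConfig | None = None) -> tuple[float, float]:
    """Mean node BC over the anterior and the posterior electrode sets."""
    regions = regions or RegionConfig()
    node_set = set(tree.nodes)
    for name, labels in (("anterior", regions.anterior),
                         ("posterior", regions.posterior)):
        unknown = set(labels) - node_set
        if unknown:
            raise ValueError(f"{name} region lists unknown nodes: {sorted(unknown)}")
    bc, _, _ = betweenness(tree)
    ant = float(np.mean([bc[l] for l in regions.anterior]))
    post = float(np.mean([bc[l] for l in regions.posterior]))
    return ant, post


def tree_metrics(tree: SpanningTree,
                 regions: RegionConfig | None = None) -> MSTMetrics:
    """All global and regional metrics of one tree."""
    _, max_deg = degree_metrics(tree)
    leaves, leaf_frac = leaf_metrics(tree)
    d = diameter(tree)
    m = tree.n - 1
    assert 2 <= leaves <= m and d <= m - leaves + 2
    _, bc_max, bc_global = betweenness(tree)
    try:
        ant, post = regional_bc(tree, regions)
    except ValueError:
        ant = post = float("nan")  # montage without the standard regions
    return MSTMetrics(
        max_degree=max_deg,
        leaf_number=leaves,
        leaf_fraction=leaf_frac,
        diameter=d,
        diameter_norm=d / m,
        bc_max=bc_max,
        bc_global=bc_global,
        degree_correlation=degree_correlation(tree),
        bc_anterior=ant,
        bc_posterior=post,
    )


def average_metrics(per_epoch: list[MSTMetrics]) -> MSTMetrics:
    """Arithmetic mean of every metric field across epochs."""
    if not per_epoch:
        raise ValueError("no metrics to average")
    return MSTMetrics(**{
        f.name: float(np.mean([getattr(p, f.name) for p in per_epoch]))
        for f in fields(MSTMetrics)
    })


def subject_band_metrics(epochs, regions: RegionConfig | None = None,
                         trim: int = 0) -> MSTMetrics:
    """Per-epoch PLI -> per-epoch tree -> metrics, averaged across epochs."""
    from .connectivity import epochs_pli

    mats = epochs_pli(epochs, trim=trim)
    if not mats:
        raise ValueError("epoch set is empty")
    per_epoch = [tree_metrics(max_spanning_tree(m), regions) for m in mats]
    return average_metrics(per_epoch)


def plot_tree(tree: SpanningTree, ax=None, regions: RegionConfig | None = None):
    """Quick-look drawing: node size by degree, hubs highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    g = tree.to_networkx()
    bc, bc_max, _ = betweenness(tree)
    pos = nx.kamada_kawai_layout(g)
    sizes = [120 + 600 * bc[n] for n in g.nodes]
    colors = ["tab:red" if bc[n] == bc_max else
              "lightgreen" if g.degree(n) == 1 else "tab:blue"
              for n in g.nodes]
    widths = [1 + 3 * d.get("weight", 0.0) for _, _, d in g.edges(data=True)]
    nx.draw_networkx(g, pos=pos, ax=ax, node_size=sizes, node_color=colors,
                     width=widths, font_size=7)
    ax.set_axis_off()
    return ax
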
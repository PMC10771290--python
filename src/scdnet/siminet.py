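"""Spatial graph-edit similarity between brain networks.

The similarity between two spatially embedded weighted graphs is built
from two cost components.

Node stage (four operations):
  (i)   common nodes — pairs within ``epsilon`` of each other, cost 0;
  (ii)  substitution — remaining cross pairs matched greedily
        nearest-first with cost equal to their Euclidean distance
        normalized by the coordinate-space diameter, chosen only when
        that normalized distance is below the insertion cost;
  (iii) insertion — unmatched nodes of the second graph, constant cost
        ``c_ins`` each;
  (iv)  deletion — unmatched nodes of the first graph, same constant.

Edge stage: the node correspondence maps edges of one graph onto the
other; the cost is the sum of absolute weight differences over the union
of edges (an edge absent on one side contributes its full weight).

Both costs are normalized against the empty-overlap reference (every node
inserted/deleted, every unit of edge weight unmatched) and combined with
mixing weight ``alpha``; the index is 1 minus the combined cost, so two
identical networks score exactly 1 and two networks with nothing in
common score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import ROIAtlas
from .connectivity import ConnectivityMatrix

__all__ = [
    "SpatialGraph",
    "SimilarityResult",
    "node_edit_costs",
    "edge_distance",
    "similarity_index",
    "graph_from_adjacency",
]


@dataclass
class SpatialGraph:
    """Weighted undirected graph whose nodes carry 3-D coordinates."""

    nodes: dict[str, np.ndarray]  # id -> coordinate (3,)
    edges: dict[tuple[str, str], float]  # sorted id pair -> weight in [0, 1]

    def __post_init__(self) -> None:
        self.nodes = {str(k): np.asarray(v, dtype=float) for k, v in self.nodes.items()}
        for k, v in self.nodes.items():
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"node {k!r} needs a finite 3-D coordinate")
        canon = {}
        for (a, b), w in self.edges.items():
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) references a missing node")
            if a == b:
                raise ValueError("self-loops are not allowed")
            if not (0.0 <= w <= 1.0):
                raise ValueError("edge weights must lie in [0, 1]")
            canon[tuple(sorted((a, b)))] = float(w)
        self.edges = canon

    @property
    def total_edge_weight(self) -> float:
        return float(sum(self.edges.values()))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class NodeCorrespondence:
    mapping: dict[str, str]  # g1 id -> g2 id (common + substituted)
    n_common: int
    n_substituted: int
    n_inserted: int
    n_deleted: int


@dataclass(frozen=True)
class SimilarityResult:
    node_cost: float
    edge_cost: float
    index: float
    n_common: int
    n_substituted: int
    n_inserted: int
    n_deleted: int

    def breakdown(self) -> dict[str, int]:
        return {
            "common": self.n_common,
            "substituted": self.n_substituted,
            "inserted": self.n_inserted,
            "deleted": self.n_deleted,
        }


def _diameter(coords: np.ndarray) -> float:
    if coords.shape[0] < 2:
        return 0.0
    diffs = coords[:, None, :] - coords[None, :, :]
    return float(np.sqrt((diffs**2).sum(-1)).max())


def _sorted_cross_pairs(g1: SpatialGraph, g2: SpatialGraph):
    """Cross node pairs sorted by (distance, label pair) for determinism."""
    ids1 = sorted(g1.nodes)
    ids2 = sorted(g2.nodes)
    pairs = []
    for a in ids1:
        ca = g1.nodes[a]
        for b in ids2:
            d = float(np.linalg.norm(ca - g2.nodes[b]))
            key = (d,) + tuple(sorted((a, b)))
            pairs.append((key, d, a, b))
    pairs.sort(key=lambda t: t[0])
    return pairs


def node_edit_costs(
    g1: SpatialGraph,
    g2: SpatialGraph,
    epsilon: float = 0.0,
    c_ins: float = 1.0,
    diameter: float | None = None,
) -> tuple[float, NodeCorrespondence]:
    """Greedy node-edit cost between two spatial graphs.

    Returns the total node cost and the resulting node correspondence.
    ``diameter`` normalizes substitution distances; by default it is the
    diameter of the union of both node sets.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if c_ins <= 0:
        raise ValueError("c_ins must be positive")
    if diameter is None:
        all_coords = np.array(
            [*g1.nodes.values(), *g2.nodes.values()], dtype=float
        ).reshape(-1, 3)
        diameter = _diameter(all_coords)

    used1: set[str] = set()
    used2: set[str] = set()
    mapping: dict[str, str] = {}
    n_common = 0
    n_sub = 0
    cost = 0.0
    for _, d, a, b in _sorted_cross_pairs(g1, g2):
        if a in used1 or b in used2:
            continue
        if d <= epsilon:
            used1.add(a)
            used2.add(b)
            mapping[a] = b
            n_common += 1
            continue
        d_norm = d / diameter if diameter > 0 else 0.0
        if d_norm < c_ins:  # substitution only when cheaper than re-insertion
            used1.add(a)
            used2.add(b)
            mapping[a] = b
            n_sub += 1
            cost += d_norm
    n_del = g1.n_nodes - len(used1)
    n_ins = g2.n_nodes - len(used2)
    cost += c_ins * (n_del + n_ins)
    return cost, NodeCorrespondence(
        mapping=mapping,
        n_common=n_common,
        n_substituted=n_sub,
        n_inserted=n_ins,
        n_deleted=n_del,
    )


def edge_distance(
    g1: SpatialGraph,
    g2: SpatialGraph,
    correspondence: NodeCorrespondence | None = None,
) -> float:
    """Sum of |w1 - w2| over corresponding edges (absent edge = weight 0)."""
    if correspondence is None:
        _, correspondence = node_edit_costs(g1, g2)
    mapping = correspondence.mapping
    matched2: set[tuple[str, str]] = set()
    cost = 0.0
    for (a, b), w1 in g1.edges.items():
        ma, mb = mapping.get(a), mapping.get(b)
        if ma is not None and mb is not None:
            key = tuple(sorted((ma, mb)))
            w2 = g2.edges.get(key, 0.0)
            if key in g2.edges:
                matched2.add(key)
            cost += abs(w1 - w2)
        else:
            cost += w1
    for key, w2 in g2.edges.items():
        if key not in matched2:
            cost += w2
    return cost


def similarity_index(
    g1: SpatialGraph,
    g2: SpatialGraph,
    alpha: float = 0.5,
    epsilon: float = 0.0,
    c_ins: float = 1.0,
    diameter: float | None = None,
) -> SimilarityResult:
    """Normalized spatial similarity index in [0, 1].

    ``alpha`` balances node against edge cost.  Normalization uses the
    empty-overlap reference: node cost (|V1| + |V2|) * c_ins, edge cost
    sum(w1) + sum(w2).  Identical graphs score exactly 1.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if g1.n_nodes == 0 and g2.n_nodes == 0:
        raise ValueError("similarity of two empty graphs is undefined")
    node_cost, corr = node_edit_costs(
        g1, g2, epsilon=epsilon, c_ins=c_ins, diameter=diameter
    )
    edge_cost = edge_distance(g1, g2, corr)
    max_node = (g1.n_nodes + g2.n_nodes) * c_ins
    max_edge = g1.total_edge_weight + g2.total_edge_weight
    node_term = node_cost / max_node if max_node > 0 else 0.0
    edge_term = edge_cost / max_edge if max_edge > 0 else 0.0
    total = alpha * node_term + (1.0 - alpha) * edge_term
    index = float(np.clip(1.0 - total, 0.0, 1.0))
    return SimilarityResult(
        node_cost=float(node_cost),
        edge_cost=float(edge_cost),
        index=index,
        n_common=corr.n_common,
        n_substituted=corr.n_substituted,
        n_inserted=corr.n_inserted,
        n_deleted=corr.n_deleted,
    )


def graph_from_adjacency(
    matrix: ConnectivityMatrix,
    atlas: ROIAtlas,
    threshold_prop: float = 0.2,
) -> SpatialGraph:
    """Spatial graph from an atlas-aligned adjacency.

    The adjacency is proportionally thresholded (the strongest
    ``threshold_prop`` fraction of off-diagonal weights is kept) and a
    node is present iff its thresholded degree is positive — on a fixed
    atlas every network would otherwise contain all nodes and the node
    stage would be vacuous.
    """
    if not (0.0 < threshold_prop <= 1.0):
        raise ValueError("threshold_prop must lie in (0, 1]")
    if matrix.roi_order != atlas.roi_ids:
        raise ValueError("adjacency ROI order must match the atlas")
    v = matrix.values
    n = v.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = v[iu, ju]
    nz = weights[weights > 0]
    if nz.size == 0:
        return SpatialGraph(nodes={}, edges={})
    k = max(1, int(round(threshold_prop * weights.size)))
    cutoff = np.sort(weights)[::-1][min(k, weights.size) - 1]
    coords = atlas.coordinate_map()
    edges = {}
    present: set[str] = set()
    for i, j, w in zip(iu, ju, weights):
        if w >= cutoff and w > 0:
            a, b = matrix.roi_order[i], matrix.roi_order[j]
            edges[tuple(sorted((a, b)))] = float(w)
            present.add(a)
            present.add(b)
    nodes = {r: coords[r] for r in sorted(present)}
    return SpatialGraph(nodes=nodes, edges=edges)
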
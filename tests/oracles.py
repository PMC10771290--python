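"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_betweenness(weights: np.ndarray) -> np.ndarray:
    """Unnormalized weighted betweenness by exhaustive simple-path search.

    Edge length is 1/weight; for every ordered node pair all simple paths
    are enumerated, the shortest length found, and every shortest path
    credits its interior nodes with 1/(number of shortest paths).  Each
    unordered pair is counted once (undirected convention).
    """
    n = weights.shape[0]
    lengths = {}
    for i in range(n):
        for j in range(i + 1, n):
            if weights[i, j] > 0:
                lengths[(i, j)] = lengths[(j, i)] = 1.0 / weights[i, j]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            # enumerate all simple paths s -> t by DFS
            best = np.inf
            shortest_paths: list[tuple[int, ...]] = []
            stack = [(s, (s,), 0.0)]
            while stack:
                node, path, dist = stack.pop()
                if dist > best + 1e-12:
                    continue
                if node == t:
                    if dist < best - 1e-12:
                        best = dist
                        shortest_paths = [path]
                    elif abs(dist - best) <= 1e-12:
                        shortest_paths.append(path)
                    continue
                for nxt in range(n):
                    if (node, nxt) in lengths and nxt not in path:
                        stack.append((nxt, path + (nxt,), dist + lengths[(node, nxt)]))
            if not shortest_paths:
                continue
            credit = 1.0 / len(shortest_paths)
            for path in shortest_paths:
                for interior in path[1:-1]:
                    bc[interior] += credit
    return bc


def random_connected_weighted_graph(
    rng: np.random.Generator, n: int, density: float = 0.5
) -> np.ndarray:
    """Random symmetric weighted adjacency guaranteed connected."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        if w[a, b] == 0:
            w[a, b] = w[b, a] = rng.uniform(0.1, 1.0)
    return w


def reference_similarity(
    nodes1: dict, edges1: dict, nodes2: dict, edges2: dict,
    alpha: float = 0.5, c_ins: float = 1.0, epsilon: float = 0.0,
    diameter: float | None = None,
) -> float:
    """Step-by-step reference of the four-stage spatial similarity.

    Written independently of the package implementation: explicit loops,
    no shared helpers.  Used to freeze expected values for fixtures.
    """
    import math

    coords = list(nodes1.values()) + list(nodes2.values())
    if diameter is None:
        diameter = 0.0
        for a, b in itertools.combinations(coords, 2):
            d = math.dist(a, b)
            diameter = max(diameter, d)

    # stage 1+2: greedy common/substitution matching, nearest first
    pairs = []
    for a, ca in nodes1.items():
        for b, cb in nodes2.items():
            pairs.append((math.dist(ca, cb), *sorted((str(a), str(b))), a, b))
    pairs.sort(key=lambda t: t[:3])
    used1, used2, mapping = set(), set(), {}
    node_cost = 0.0
    n_common = 0
    for d, _, _, a, b in pairs:
        if a in used1 or b in used2:
            continue
        if d <= epsilon:
            used1.add(a); used2.add(b); mapping[a] = b; n_common += 1
        else:
            dn = d / diameter if diameter > 0 else 0.0
            if dn < c_ins:
                used1.add(a); used2.add(b); mapping[a] = b
                node_cost += dn
    # stages 3+4: insertion / deletion
    node_cost += c_ins * (len(nodes1) - len(used1))
    node_cost += c_ins * (len(nodes2) - len(used2))

    # edge stage
    edge_cost = 0.0
    seen2 = set()
    for (a, b), w1 in edges1.items():
        ma, mb = mapping.get(a), mapping.get(b)
        if ma is not None and mb is not None:
            key = tuple(sorted((ma, mb)))
            w2 = edges2.get(key, 0.0)
            if key in edges2:
                seen2.add(key)
            edge_cost += abs(w1 - w2)
        else:
            edge_cost += w1
    for key, w2 in edges2.items():
        if key not in seen2:
            edge_cost += w2

    max_node = (len(nodes1) + len(nodes2)) * c_ins
    max_edge = sum(edges1.values()) + sum(edges2.values())
    node_term = node_cost / max_node if max_node > 0 else 0.0
    edge_term = edge_cost / max_edge if max_edge > 0 else 0.0
    return max(0.0, min(1.0, 1.0 - (alpha * node_term + (1 - alpha) * edge_term)))
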
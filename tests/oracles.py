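"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by the most direct method available
(double loops, exhaustive enumeration, dense matrix algorithms) without
touching the package's own code paths for that quantity.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.sparse.csgraph import floyd_warshall
import networkx as nx


def modularity_bruteforce(g: nx.Graph, partition: dict) -> float:
    """Pairwise double sum (1/2m) Σ_ij [A_ij - k_i k_j / 2m] δ(c_i, c_j)."""
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    two_m = a.sum()
    k = a.sum(axis=1)
    q = 0.0
    for i in range(len(nodes)):
        for j in range(len(nodes)):
            if partition[nodes[i]] == partition[nodes[j]]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def cohesiveness_bruteforce(g: nx.Graph, V: set, penalty_per_node: float) -> float:
    """f(V) by direct classification of every edge as internal or boundary."""
    w_in = w_bound = 0.0
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1)
        inside = (u in V) + (v in V)
        if inside == 2:
            w_in += w
        elif inside == 1:
            w_bound += w
    denom = w_in + w_bound + penalty_per_node * len(V)
    return w_in / denom if denom > 0 else 0.0


def jaccard_layer_bruteforce(attribute_map: dict, cutoff: float) -> dict:
    """All-pairs double loop over entities with direct set arithmetic."""
    entities = sorted(attribute_map)
    edges = {}
    for i, a in enumerate(entities):
        for b in entities[i + 1 :]:
            sa, sb = attribute_map[a], attribute_map[b]
            union = len(sa | sb)
            if union == 0:
                continue
            j = len(sa & sb) / union
            if j >= cutoff:
                edges[(a, b)] = j
    return edges


def hypergeom_tail_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every n-subset of an N-element universe whose
    first K elements are the 'feature' genes."""
    feature = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(feature & set(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


def all_pairs_distances_fw(g: nx.Graph) -> dict:
    """Unweighted all-pairs shortest paths via dense Floyd-Warshall."""
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    d = floyd_warshall(a, directed=False, unweighted=True)
    out = {}
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            out[(u, v)] = None if math.isinf(d[i, j]) else int(d[i, j])
    return out


def set_partitions(items: list):
    """Every partition of ``items`` into non-empty blocks (for exhaustive
    modularity search on tiny graphs)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_partition_exhaustive(g: nx.Graph) -> tuple[float, list]:
    """Globally optimal modularity over all partitions (tiny graphs only)."""
    nodes = list(g.nodes)
    best_q, best = -math.inf, None
    for blocks in set_partitions(nodes):
        part = {n: i for i, block in enumerate(blocks) for n in block}
        q = modularity_bruteforce(g, part)
        if q > best_q:
            best_q, best = q, blocks
    return best_q, best


def random_weighted_graph(rng: np.random.Generator, n_nodes: int, p: float = 0.4) -> nx.Graph:
    """Connected-ish random weighted test graph with integer weights 1-4."""
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                g.add_edge(i, j, weight=int(rng.integers(1, 5)))
    if g.number_of_edges() == 0:
        g.add_edge(0, 1 % n_nodes if n_nodes > 1 else 0, weight=1)
    return g
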
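"""Module detection on the weighted heterogeneous network.

Two algorithms, both implemented from their objective functions:

* **Louvain modularity optimisation** — greedy two-phase maximisation of
  Newman-Girvan modularity Q = (1/2m) Σ_ij [A_ij - k_i k_j / 2m] δ(c_i, c_j):
  local single-node moves to the neighbouring community with the largest
  positive gain, followed by aggregation of communities into a weighted
  super-graph, repeated until no further gain.  Produces a disjoint
  partition covering every node.

* **Cohesive overlapping clustering** (ClusterONE-style) — greedy growth of
  clusters maximising cohesiveness f(V) = W_in / (W_in + W_bound + P(V)),
  where W_in is the total internal edge weight, W_bound the total weight on
  the boundary, and P(V) = penalty_per_node * |V| penalises unobserved
  connectivity.  Grown clusters may overlap; highly overlapping ones are
  merged and the result is filtered by size, internal density, and a
  one-sided Mann-Whitney test of internal vs boundary edge weights.
"""

from __future__ import annotations

import itertools
import logging
import random
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy.stats import mannwhitneyu

from .network import WeightedHetNet

log = logging.getLogger(__name__)

#: pass-level absolute modularity-gain tolerance for Louvain termination
LOUVAIN_TOL = 1e-10
#: strict-improvement margin for greedy moves (float-noise guard)
_EPS = 1e-12

_MAX_SWEEPS = 10_000


def _as_graph(net: WeightedHetNet | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, WeightedHetNet) else net


# ---------------------------------------------------------------------------
# modularity


def modularity(net: WeightedHetNet | nx.Graph, partition: Mapping[str, int]) -> float:
    """Weighted modularity Q of a partition on a loop-free graph.

    Computed via per-community sums, algebraically identical to the pairwise
    double sum over (A_ij - k_i k_j / 2m) δ(c_i, c_j).
    """
    g = _as_graph(net)
    m = g.size(weight="weight")
    if m == 0:
        raise ValueError("empty network: modularity undefined (m = 0)")
    missing = [n for n in g.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    if any(u == v for u, v in g.edges):
        raise ValueError("modularity is defined here for loop-free graphs only")
    w_in = 0.0
    for u, v, w in g.edges(data="weight", default=1):
        if partition[u] == partition[v]:
            w_in += w
    deg_sum: dict[int, float] = defaultdict(float)
    for n, k in g.degree(weight="weight"):
        deg_sum[partition[n]] += k
    expected = sum((d / (2.0 * m)) ** 2 for d in deg_sum.values())
    return w_in / m - expected


@dataclass(frozen=True)
class Partition:
    """A disjoint node partition with its modularity and the Louvain level
    history (each level a (membership, Q) pair, Q non-decreasing)."""

    membership: dict[str, int]
    q: float
    levels: tuple[tuple[dict[str, int], float], ...] = ()

    def communities(self) -> list[frozenset[str]]:
        groups: dict[int, set[str]] = defaultdict(set)
        for n, c in self.membership.items():
            groups[c].add(n)
        return [frozenset(groups[c]) for c in sorted(groups)]

    def to_cluster_set(self) -> "ClusterSet":
        comms = self.communities()
        return ClusterSet(
            algorithm="louvain",
            clusters=comms,
            meta=[{"size": len(c)} for c in comms],
        )


def _one_level(g: nx.Graph, rng: random.Random) -> dict:
    """Single Louvain phase: greedy local moves until a full sweep moves
    nothing.  Handles self-loops from community aggregation (a self-loop of
    weight w counts 2w toward the node's degree, never toward neighbour
    gains)."""
    two_m = sum(k for _, k in g.degree(weight="weight"))
    deg = dict(g.degree(weight="weight"))
    comm = {n: i for i, n in enumerate(sorted(g.nodes, key=str))}
    comm_tot = {comm[n]: deg[n] for n in g.nodes}
    for _ in range(_MAX_SWEEPS):
        moved = 0
        order = sorted(g.nodes, key=str)
        rng.shuffle(order)
        for u in order:
            cu = comm[u]
            nbw: dict[int, float] = defaultdict(float)
            for v, d in g[u].items():
                if v != u:
                    nbw[comm[v]] += d.get("weight", 1)
            comm_tot[cu] -= deg[u]
            stay_gain = nbw.get(cu, 0.0) - deg[u] * comm_tot[cu] / two_m
            best_c, best_gain = cu, stay_gain
            for c in sorted(nbw):
                if c == cu:
                    continue
                gain = nbw[c] - deg[u] * comm_tot[c] / two_m
                if gain > best_gain + _EPS:
                    best_c, best_gain = c, gain
            comm_tot[best_c] = comm_tot.get(best_c, 0.0) + deg[u]
            if best_c != cu:
                comm[u] = best_c
                moved += 1
        if moved == 0:
            break
    return comm


def _aggregate(g: nx.Graph, comm: Mapping) -> nx.Graph:
    """Collapse communities into super-nodes; internal weight becomes a
    self-loop."""
    agg = nx.Graph()
    agg.add_nodes_from(sorted(set(comm.values())))
    for u, v, w in g.edges(data="weight", default=1):
        cu, cv = comm[u], comm[v]
        if agg.has_edge(cu, cv):
            agg[cu][cv]["weight"] += w
        else:
            agg.add_edge(cu, cv, weight=w)
    return agg


def louvain(net: WeightedHetNet | nx.Graph, seed: int = 0) -> Partition:
    """Two-phase Louvain modularity optimisation.

    Node visit order is a seeded shuffle per sweep; among equal-gain moves
    the current community is kept, so runs are reproducible under a fixed
    seed.  Terminates when an aggregation pass improves Q by less than
    ``LOUVAIN_TOL``; returns the flat partition of the final (highest-Q)
    level with the full level history attached.
    """
    g0 = _as_graph(net)
    if g0.number_of_nodes() == 0:
        raise ValueError("empty network")
    rng = random.Random(seed)
    graph = g0.copy()
    node_map: dict = {n: {n} for n in graph.nodes}
    levels: list[tuple[dict[str, int], float]] = []
    singleton = {n: i for i, n in enumerate(sorted(g0.nodes, key=str))}
    q_prev = modularity(g0, singleton)
    while True:
        comm = _one_level(graph, rng)
        flat = {orig: comm[sup] for sup, origs in node_map.items() for orig in origs}
        flat = _canonical(flat)
        q = modularity(g0, flat)
        if levels and q <= levels[-1][1] + LOUVAIN_TOL:
            break
        if not levels and q < q_prev - LOUVAIN_TOL:
            # a level can never be worse than the singleton start
            flat, q = _canonical(singleton), q_prev
        levels.append((flat, q))
        agg = _aggregate(graph, comm)
        if agg.number_of_nodes() == graph.number_of_nodes():
            break
        new_map: dict = defaultdict(set)
        for sup, origs in node_map.items():
            new_map[comm[sup]] |= origs
        node_map = dict(new_map)
        graph = agg
    if not levels:
        levels = [(_canonical(singleton), q_prev)]
    membership, q = levels[-1]
    return Partition(membership=membership, q=q, levels=tuple(levels))


def _canonical(membership: Mapping[str, int]) -> dict[str, int]:
    """Relabel communities 0..k-1 in order of their smallest member id."""
    reps: dict[int, str] = {}
    for n in sorted(membership, key=str):
        reps.setdefault(membership[n], n)
    order = {c: i for i, (c, _) in enumerate(sorted(reps.items(), key=lambda cr: str(cr[1])))}
    return {n: order[c] for n, c in membership.items()}


# ---------------------------------------------------------------------------
# cohesive overlapping clustering


@dataclass(frozen=True)
class CohesiveCluster:
    """A node set with its cohesiveness decomposition."""

    nodes: frozenset[str]
    w_in: float
    w_bound: float
    penalty: float
    f: float
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"cohesiveness out of range: {self.f}")


def _cohesion(w_in: float, w_bound: float, penalty: float) -> float:
    denom = w_in + w_bound + penalty
    return w_in / denom if denom > 0 else 0.0


def cohesiveness(
    net: WeightedHetNet | nx.Graph,
    nodes: Iterable[str],
    penalty_per_node: float = 0.0,
) -> CohesiveCluster:
    """Cohesiveness f(V) = W_in / (W_in + W_bound + penalty_per_node * |V|)
    by direct summation over edges."""
    g = _as_graph(net)
    V = frozenset(nodes)
    if not V:
        raise ValueError("empty node set")
    unknown = V - set(g.nodes)
    if unknown:
        raise ValueError(f"unknown nodes: {sorted(unknown)[:5]}")
    w_in = w_bound = 0.0
    for u, v, w in g.edges(data="weight", default=1):
        inside = (u in V) + (v in V)
        if inside == 2:
            w_in += w
        elif inside == 1:
            w_bound += w
    penalty = penalty_per_node * len(V)
    return CohesiveCluster(V, w_in, w_bound, penalty, _cohesion(w_in, w_bound, penalty))


@dataclass(frozen=True)
class ClusterSet:
    """Node groups from one algorithm: disjoint for Louvain, possibly
    overlapping for the cohesive clusterer; ``meta`` holds per-cluster
    quality records aligned with ``clusters``."""

    algorithm: str
    clusters: list[frozenset[str]]
    meta: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)


def _grow(g: nx.Graph, seed_node: str, deg: Mapping[str, float], penalty: float) -> frozenset[str]:
    """Greedily grow a cluster from one seed: apply the single boundary-node
    addition or member removal that most increases f(V), until none does."""
    V = {seed_node}
    w_in, w_bound = 0.0, deg[seed_node]
    f = _cohesion(w_in, w_bound, penalty * len(V))
    while True:
        best_f, best_move = f, None
        boundary = sorted({v for u in V for v in g[u] if v not in V}, key=str)
        for v in boundary:
            wv = sum(d.get("weight", 1) for u, d in g[v].items() if u in V)
            nf = _cohesion(w_in + wv, w_bound - wv + (deg[v] - wv), penalty * (len(V) + 1))
            if nf > best_f + _EPS:
                best_f, best_move = nf, ("add", v, wv)
        if len(V) > 1:
            for v in sorted(V, key=str):
                wv = sum(d.get("weight", 1) for u, d in g[v].items() if u in V)
                nf = _cohesion(w_in - wv, w_bound + wv - (deg[v] - wv), penalty * (len(V) - 1))
                if nf > best_f + _EPS:
                    best_f, best_move = nf, ("remove", v, wv)
        if best_move is None:
            return frozenset(V)
        op, v, wv = best_move
        if op == "add":
            V.add(v)
            w_in += wv
            w_bound += deg[v] - 2 * wv
        else:
            V.remove(v)
            w_in -= wv
            w_bound += 2 * wv - deg[v]
        f = best_f


def match_coefficient(a: frozenset[str], b: frozenset[str]) -> float:
    """Overlap score |A ∩ B|² / (|A| · |B|) used for cluster merging."""
    inter = len(a & b)
    return inter * inter / (len(a) * len(b)) if a and b else 0.0


def _merge_overlapping(clusters: list[frozenset[str]], threshold: float) -> list[frozenset[str]]:
    merged = sorted(set(clusters), key=lambda c: (-len(c), sorted(c)))
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(merged)), 2):
            if match_coefficient(merged[i], merged[j]) >= threshold:
                union = merged[i] | merged[j]
                merged = [c for k, c in enumerate(merged) if k not in (i, j)] + [union]
                merged.sort(key=lambda c: (-len(c), sorted(c)))
                changed = True
                break
    return merged


def _weight_significance(g: nx.Graph, V: frozenset[str]) -> float:
    """One-sided Mann-Whitney p-value that internal edge weights exceed
    boundary edge weights; 0 by convention when the cluster has no boundary."""
    internal, boundary = [], []
    for u, v, w in g.edges(data="weight", default=1):
        inside = (u in V) + (v in V)
        if inside == 2:
            internal.append(w)
        elif inside == 1:
            boundary.append(w)
    if not boundary:
        log.debug("cluster %s has no boundary edges; p := 0", sorted(V)[:3])
        return 0.0
    if not internal:
        return 1.0
    return float(mannwhitneyu(internal, boundary, alternative="greater").pvalue)


def clusterone(
    net: WeightedHetNet | nx.Graph,
    penalty_per_node: float = 2.0,
    min_size: int = 3,
    min_density: float = 0.3,
    overlap_merge_threshold: float = 0.8,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterSet:
    """Greedy cohesive clustering with overlap.

    Seeds at the highest-weighted-degree node not yet in any cluster, grows
    to a local maximum of f(V), and repeats until every node has been
    covered.  Cluster pairs with match coefficient >= the merge threshold
    are merged; clusters below ``min_size`` or with internal weighted
    density below ``min_density``, or whose internal-vs-boundary weight
    p-value exceeds ``alpha``, are discarded.  Fully deterministic (the seed
    parameter is accepted for interface symmetry; ties are broken by node
    id).
    """
    if min_size < 1 or penalty_per_node < 0 or not 0 < overlap_merge_threshold <= 1:
        raise ValueError("invalid cohesive-clustering parameters")
    g = _as_graph(net)
    deg = dict(g.degree(weight="weight"))
    unclustered = set(g.nodes)
    grown: list[frozenset[str]] = []
    for s in sorted(g.nodes, key=lambda n: (-deg[n], str(n))):
        if s not in unclustered:
            continue
        V = _grow(g, s, deg, penalty_per_node)
        grown.append(V)
        unclustered -= V
    merged = _merge_overlapping(grown, overlap_merge_threshold)
    clusters: list[frozenset[str]] = []
    meta: list[dict] = []
    for V in merged:
        if len(V) < min_size:
            continue
        cc = cohesiveness(g, V, penalty_per_node)
        # weighted internal density; a singleton has no internal pairs
        density = cc.w_in / (len(V) * (len(V) - 1) / 2.0) if len(V) > 1 else 0.0
        if density < min_density:
            continue
        p = _weight_significance(g, V)
        if p > alpha:
            continue
        clusters.append(V)
        meta.append(
            {
                "size": len(V),
                "w_in": cc.w_in,
                "w_bound": cc.w_bound,
                "f": cc.f,
                "density": density,
                "pvalue": p,
            }
        )
    log.info(
        "cohesive clustering: %d grown, %d after merge, %d kept",
        len(grown),
        len(merged),
        len(clusters),
    )
    return ClusterSet(algorithm="clusterone", clusters=clusters, meta=meta)


def mixed_clusters(clusters: ClusterSet, node_types: Mapping[str, str]) -> ClusterSet:
    """Retain exactly the clusters containing >=1 disease and >=1 drug."""
    kept, kept_meta = [], []
    metas = clusters.meta or [{} for _ in clusters.clusters]
    for V, m in zip(clusters.clusters, metas):
        kinds = {node_types[n] for n in V}
        if {"disease", "drug"} <= kinds:
            kept.append(V)
            kept_meta.append(m)
    return ClusterSet(algorithm=clusters.algorithm, clusters=kept, meta=kept_meta)


# ---------------------------------------------------------------------------
# exports


def write_clusters(path: str | Path, clusters: ClusterSet, node_types: Mapping[str, str]) -> None:
    """TSV export: cluster_id, algorithm, node_id, node_type."""
    with open(path, "w") as fh:
        fh.write("cluster_id\talgorithm\tnode_id\tnode_type\n")
        for i, V in enumerate(clusters.clusters):
            for n in sorted(V):
                fh.write(f"{i}\t{clusters.algorithm}\t{n}\t{node_types.get(n, 'NA')}\n")


def write_cluster_meta(path: str | Path, clusters: ClusterSet) -> None:
    """Per-cluster metadata TSV (size plus algorithm-specific quality)."""
    keys: list[str] = []
    for m in clusters.meta:
        keys += [k for k in m if k not in keys]
    with open(path, "w") as fh:
        fh.write("cluster_id\talgorithm\t" + "\t".join(keys) + "\n")
        for i, m in enumerate(clusters.meta):
            vals = "\t".join(f"{m.get(k, '')}" for k in keys)
            fh.write(f"{i}\t{clusters.algorithm}\t{vals}\n")


def read_clusters(path: str | Path) -> ClusterSet:
    """Read the TSV written by :func:`write_clusters`."""
    groups: dict[int, set[str]] = defaultdict(set)
    algorithm = "unknown"
    with open(path) as fh:
        fh.readline()
        for line in fh:
            cid, algorithm, node, _ = line.rstrip("\n").split("\t")
            groups[int(cid)].add(node)
    clusters = [frozenset(groups[c]) for c in sorted(groups)]
    return ClusterSet(algorithm=algorithm, clusters=clusters, meta=[{"size": len(c)} for c in clusters])
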
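"""Weighted heterogeneous disease-drug network construction.

Four similarity layers are computed over all entity pairs (disease-disease,
disease-drug, drug-drug): a gene layer from annotation sets and three feature
layers from enrichment profiles.  Each layer keeps pairs whose Jaccard index
is at least the cutoff (default 0.5, boundary inclusive).  The network is the
union of the surviving pairs; an edge's integer weight is the number of
layers (1-4) in which the pair survived.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .corpus import GENE_LAYER, LAYERS

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.5

Pair = tuple[str, str]


def _key(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|a ∩ b| / |a ∪ b|; defined as 0 when both sets are empty."""
    if not a and not b:
        return 0.0
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


@dataclass(frozen=True)
class SimilarityLayer:
    """Thresholded Jaccard edges for one annotation category."""

    label: str
    edges: dict[Pair, float]

    def __post_init__(self) -> None:
        for (a, b), v in self.edges.items():
            if a == b:
                raise ValueError(f"self-pair in layer {self.label}: {a}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"Jaccard value out of range: {v}")


def build_layer(
    attribute_map: Mapping[str, frozenset[str]],
    label: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> SimilarityLayer:
    """All-pairs Jaccard over an entity -> id-set map, thresholded at cutoff.

    Uses an inverted index (id -> entities) so only pairs with a non-empty
    intersection are scored; the result is identical to the brute-force
    double loop.  Entities with empty sets never form edges.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    index: dict[str, list[str]] = defaultdict(list)
    for entity, ids in attribute_map.items():
        for i in ids:
            index[i].append(entity)
    candidates: set[Pair] = set()
    for members in index.values():
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                candidates.add((a, b))
    edges = {}
    for a, b in candidates:
        v = jaccard(attribute_map[a], attribute_map[b])
        if v >= cutoff:
            edges[(a, b)] = v
    return SimilarityLayer(label=label, edges=edges)


@dataclass
class WeightedHetNet:
    """Undirected weighted graph over typed disease/drug nodes.

    Backed by a :class:`networkx.Graph`; node attribute ``kind`` is
    ``"disease"`` or ``"drug"``, edge attributes are ``weight`` (1-4) and
    ``layers`` (tuple of contributing layer labels, ``len == weight``).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def total_edge_weight(self) -> float:
        """m = half the sum of weighted degrees."""
        return self.graph.size(weight="weight")

    def weighted_degree(self, node: str) -> float:
        return self.graph.degree(node, weight="weight")

    @property
    def node_types(self) -> dict[str, str]:
        return {n: d["kind"] for n, d in self.graph.nodes(data=True)}

    def edge_weights(self) -> dict[Pair, int]:
        return {_key(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}

    def copy(self) -> "WeightedHetNet":
        return WeightedHetNet(self.graph.copy())


def assemble_network(
    layers: Iterable[SimilarityLayer],
    node_types: Mapping[str, str],
    keep_isolated: bool = False,
) -> WeightedHetNet:
    """Union the layers into a weighted network.

    An edge exists iff the pair survives in >=1 layer; its weight is the
    number of surviving layers, recorded alongside their labels.  Nodes
    without edges are dropped unless ``keep_isolated``.
    """
    layers = list(layers)
    labels = [lay.label for lay in layers]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate layer labels: {labels}")
    contrib: dict[Pair, list[str]] = defaultdict(list)
    for lay in layers:
        for pair in lay.edges:
            contrib[pair].append(lay.label)
    g = nx.Graph()
    for (a, b), labs in contrib.items():
        for n in (a, b):
            if n not in node_types:
                raise ValueError(f"entity {n!r} has no disease/drug type tag")
        ordered = tuple(l for l in LAYERS if l in labs) or tuple(sorted(labs))
        g.add_edge(a, b, weight=len(labs), layers=ordered)
    for n in g.nodes:
        g.nodes[n]["kind"] = node_types[n]
    if keep_isolated:
        for n, kind in node_types.items():
            if n not in g:
                g.add_node(n, kind=kind)
    log.info(
        "assembled network: %d nodes, %d edges from layers %s",
        g.number_of_nodes(),
        g.number_of_edges(),
        labels,
    )
    return WeightedHetNet(g)


@dataclass(frozen=True)
class NetworkSummary:
    n_disease_nodes: int
    n_drug_nodes: int
    n_edges: int
    n_disease_disease: int
    n_disease_drug: int
    n_drug_drug: int


def network_summary(net: WeightedHetNet) -> NetworkSummary:
    """Node and edge census of the heterogeneous network, by type."""
    types = net.node_types
    n_dd = n_dr = n_rr = 0
    for u, v in net.graph.edges:
        kinds = {types[u], types[v]}
        if kinds == {"disease"}:
            n_dd += 1
        elif kinds == {"drug"}:
            n_rr += 1
        else:
            n_dr += 1
    return NetworkSummary(
        n_disease_nodes=sum(1 for t in types.values() if t == "disease"),
        n_drug_nodes=sum(1 for t in types.values() if t == "drug"),
        n_edges=net.graph.number_of_edges(),
        n_disease_disease=n_dd,
        n_disease_drug=n_dr,
        n_drug_drug=n_rr,
    )


# ---------------------------------------------------------------------------
# exports


def write_edges(path: str | Path, net: WeightedHetNet) -> None:
    """Edge-list TSV: node_a, node_b, weight, layers (comma-joined)."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\tlayers\n")
        for u, v in sorted(_key(a, b) for a, b in net.graph.edges):
            d = net.graph.edges[u, v]
            fh.write(f"{u}\t{v}\t{d['weight']}\t{','.join(d['layers'])}\n")


def write_nodes(path: str | Path, net: WeightedHetNet) -> None:
    """Node-table TSV: node_id, node_type."""
    with open(path, "w") as fh:
        fh.write("node_id\tnode_type\n")
        for n in sorted(net.graph.nodes):
            fh.write(f"{n}\t{net.graph.nodes[n]['kind']}\n")


def read_network(edge_path: str | Path, node_path: str | Path) -> WeightedHetNet:
    """Rebuild a network from the TSVs written by write_edges/write_nodes."""
    g = nx.Graph()
    with open(node_path) as fh:
        fh.readline()
        for line in fh:
            n, kind = line.rstrip("\n").split("\t")
            g.add_node(n, kind=kind)
    with open(edge_path) as fh:
        fh.readline()
        for line in fh:
            u, v, w, layers = line.rstrip("\n").split("\t")
            g.add_edge(u, v, weight=int(w), layers=tuple(layers.split(",")))
    return WeightedHetNet(g)


def write_graphml(path: str | Path, net: WeightedHetNet) -> None:
    """GraphML export with node-type and layer attributes for graph viewers."""
    g = net.graph.copy()
    for u, v, d in g.edges(data=True):
        d["layers"] = ",".join(d["layers"])
    nx.write_graphml(g, path)
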
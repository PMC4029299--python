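"""Candidate mining and validation.

Repositioning candidates are all disease-drug combinations that co-occur in
a mixed cluster, minus known indications (which are reported separately as
"recovered known indications").  The consensus set is the intersection of
the candidates found by the two clustering algorithms.  Robustness is
assessed by repeatedly deleting a fixed fraction of network edges,
re-clustering, and measuring the fraction of original candidates recovered.
The indication-distance analysis measures, for each known disease-drug
pair, the shortest path in a protein-interaction network between any
disease gene and any drug target.
"""

from __future__ import annotations

import json
import logging
import statistics
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .cluster import ClusterSet, clusterone, louvain
from .corpus import PpiGraph
from .network import WeightedHetNet

log = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class CandidateSet:
    """Disease-drug candidate pairs mined from mixed clusters.

    ``provenance`` maps each pair to the (algorithm, cluster_id) entries that
    produced it; ``known_recovered`` holds known indications found inside
    clusters (excluded from ``pairs`` but reported); ``consensus`` flags the
    pairs found by both algorithms (empty until :func:`consensus` is
    applied).
    """

    pairs: frozenset[Pair]
    provenance: dict[Pair, tuple[tuple[str, int], ...]] = field(default_factory=dict)
    known_recovered: frozenset[Pair] = frozenset()
    algorithms: tuple[str, ...] = ()
    consensus: frozenset[Pair] = frozenset()

    def __post_init__(self) -> None:
        if self.pairs & self.known_recovered:
            raise ValueError("candidate pairs must exclude known indications")


def extract_candidates(
    clusters: ClusterSet,
    node_types: Mapping[str, str],
    known: Iterable[Pair] = (),
) -> CandidateSet:
    """All per-cluster disease x drug combinations, minus known indications.

    Clusters lacking either node type contribute nothing; a pair appearing
    in several clusters keeps one provenance entry per cluster.
    """
    known = frozenset(known)
    provenance: dict[Pair, list[tuple[str, int]]] = {}
    known_hit: set[Pair] = set()
    for cid, V in enumerate(clusters.clusters):
        kinds = {node_types[n] for n in V}
        if not {"disease", "drug"} <= kinds:
            continue
        diseases = sorted(n for n in V if node_types[n] == "disease")
        drugs = sorted(n for n in V if node_types[n] == "drug")
        for d in diseases:
            for r in drugs:
                pair = (d, r)
                if pair in known:
                    known_hit.add(pair)
                else:
                    provenance.setdefault(pair, []).append((clusters.algorithm, cid))
    return CandidateSet(
        pairs=frozenset(provenance),
        provenance={p: tuple(v) for p, v in provenance.items()},
        known_recovered=frozenset(known_hit),
        algorithms=(clusters.algorithm,),
    )


def consensus(a: CandidateSet, b: CandidateSet) -> CandidateSet:
    """Pairs found by both algorithms, with merged provenance."""
    pairs = a.pairs & b.pairs
    return CandidateSet(
        pairs=pairs,
        provenance={p: a.provenance.get(p, ()) + b.provenance.get(p, ()) for p in pairs},
        known_recovered=a.known_recovered | b.known_recovered,
        algorithms=tuple(dict.fromkeys(a.algorithms + b.algorithms)),
        consensus=pairs,
    )


def recovery_rate(original: CandidateSet | frozenset[Pair], perturbed: CandidateSet | frozenset[Pair]) -> float:
    """Fraction of original candidate pairs present in the perturbed set."""
    orig = original.pairs if isinstance(original, CandidateSet) else frozenset(original)
    pert = perturbed.pairs if isinstance(perturbed, CandidateSet) else frozenset(perturbed)
    if not orig:
        raise ValueError("original candidate set is empty")
    return len(orig & pert) / len(orig)


# ---------------------------------------------------------------------------
# robustness protocol


@dataclass(frozen=True)
class RobustnessReport:
    """Edge-removal robustness of the candidate sets.

    ``per_replicate`` maps algorithm -> recovery rate per replicate;
    ``mean_recovery`` maps algorithm -> mean over replicates.
    """

    fraction: float
    reps: int
    master_seed: int
    n_edges_removed: int
    per_replicate: dict[str, tuple[float, ...]]
    mean_recovery: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "fraction": self.fraction,
                "reps": self.reps,
                "master_seed": self.master_seed,
                "n_edges_removed": self.n_edges_removed,
                "per_replicate": {a: list(r) for a, r in self.per_replicate.items()},
                "mean_recovery": self.mean_recovery,
            },
            sort_keys=True,
        )


def _cluster_both(
    net: WeightedHetNet,
    seed: int,
    clusterone_params: Mapping | None = None,
) -> dict[str, ClusterSet]:
    params = dict(clusterone_params or {})
    return {
        "louvain": louvain(net, seed=seed).to_cluster_set(),
        "clusterone": clusterone(net, seed=seed, **params),
    }


def candidates_both(
    net: WeightedHetNet,
    known: Iterable[Pair],
    seed: int = 0,
    clusterone_params: Mapping | None = None,
) -> dict[str, CandidateSet]:
    """Cluster with both algorithms and extract candidates from each."""
    types = net.node_types
    known = frozenset(known)
    out = {}
    for alg, cs in _cluster_both(net, seed, clusterone_params).items():
        out[alg] = extract_candidates(cs, types, known)
    return out


def robustness(
    net: WeightedHetNet,
    known: Iterable[Pair],
    fraction: float = 0.1,
    reps: int = 10,
    master_seed: int = 0,
    clusterone_params: Mapping | None = None,
) -> RobustnessReport:
    """Edge-removal robustness of the repositioning candidates.

    Per replicate, ``floor(fraction * |E|)`` edges are removed uniformly at
    random (seeded from the master seed and replicate index), the pruned
    network is re-clustered with both algorithms, and candidate recovery
    against the unperturbed network is recorded.  Bit-identical across runs
    with the same master seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("removal fraction must be in (0, 1)")
    if reps < 1:
        raise ValueError("at least one replicate required")
    original = candidates_both(net, known, seed=master_seed, clusterone_params=clusterone_params)
    for alg, cand in original.items():
        if not cand.pairs:
            raise ValueError(f"original {alg} candidate set is empty; robustness undefined")
    edges = sorted(tuple(sorted(e)) for e in net.graph.edges)
    n_remove = int(fraction * len(edges))
    rates: dict[str, list[float]] = {alg: [] for alg in original}
    for r in range(reps):
        rng = np.random.default_rng([master_seed, r])
        drop_idx = rng.choice(len(edges), size=n_remove, replace=False)
        pruned = net.copy()
        pruned.graph.remove_edges_from(edges[i] for i in drop_idx)
        perturbed = candidates_both(pruned, known, seed=master_seed, clusterone_params=clusterone_params)
        for alg in original:
            rates[alg].append(recovery_rate(original[alg], perturbed[alg]))
    return RobustnessReport(
        fraction=fraction,
        reps=reps,
        master_seed=master_seed,
        n_edges_removed=n_remove,
        per_replicate={a: tuple(v) for a, v in rates.items()},
        mean_recovery={a: sum(v) / len(v) for a, v in rates.items()},
    )


# ---------------------------------------------------------------------------
# indication distances in the interactome


@dataclass(frozen=True)
class IndicationDistanceReport:
    """Shortest interactome paths between known disease-drug pairs.

    ``distances`` maps each pair to its minimum gene-to-target path length,
    or None when the pair's genes are absent from the interactome or
    mutually unreachable; mean and median cover computed pairs only.
    """

    distances: dict[Pair, int | None]
    mean: float | None
    median: float | None
    n_computed: int
    n_uncomputable: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean,
                "median": self.median,
                "n_computed": self.n_computed,
                "n_uncomputable": self.n_uncomputable,
            },
            sort_keys=True,
        )


def _multi_source_bfs(adj: Mapping[str, set[str]], sources: set[str]) -> dict[str, int]:
    dist = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def indication_distances(
    ppi: PpiGraph,
    known: Iterable[Pair],
    disease_genes: Mapping[str, frozenset[str]],
    drug_targets: Mapping[str, frozenset[str]],
) -> IndicationDistanceReport:
    """Minimum shortest-path length between any disease gene and any drug
    target, per known indication; 0 when they share a gene."""
    if not ppi.edges:
        raise ValueError("empty protein-interaction network")
    g = ppi.to_networkx()
    adj = {n: set(g[n]) for n in g.nodes}
    distances: dict[Pair, int | None] = {}
    for d, r in sorted(known):
        gs = frozenset(disease_genes.get(d, frozenset()))
        ts = frozenset(drug_targets.get(r, frozenset()))
        if gs & ts:
            distances[(d, r)] = 0
            continue
        sources = set(gs) & set(adj)
        targets = set(ts) & set(adj)
        if not sources or not targets:
            distances[(d, r)] = None
            continue
        reach = _multi_source_bfs(adj, sources)
        hits = [reach[t] for t in targets if t in reach]
        distances[(d, r)] = min(hits) if hits else None
    computed = [v for v in distances.values() if v is not None]
    n_un = sum(1 for v in distances.values() if v is None)
    return IndicationDistanceReport(
        distances=distances,
        mean=(sum(computed) / len(computed)) if computed else None,
        median=float(statistics.median(computed)) if computed else None,
        n_computed=len(computed),
        n_uncomputable=n_un,
    )


# ---------------------------------------------------------------------------
# exports


def write_candidates(
    path: str | Path,
    cands: CandidateSet,
    names: Mapping[str, str] | None = None,
) -> None:
    """TSV export: disease/drug ids and names, algorithms, cluster ids,
    consensus and known flags (recovered known indications included,
    flagged)."""
    names = names or {}
    with open(path, "w") as fh:
        fh.write(
            "disease_id\tdisease_name\tdrug_id\tdrug_name\talgorithms\tcluster_ids\tconsensus\tknown_indication\n"
        )
        for d, r in sorted(cands.pairs):
            prov = cands.provenance.get((d, r), ())
            algs = ",".join(sorted({a for a, _ in prov})) or ",".join(cands.algorithms)
            cids = ",".join(f"{a}:{c}" for a, c in prov)
            cons = "yes" if (d, r) in cands.consensus else "no"
            fh.write(
                f"{d}\t{names.get(d, d)}\t{r}\t{names.get(r, r)}\t{algs}\t{cids}\t{cons}\tno\n"
            )
        for d, r in sorted(cands.known_recovered):
            fh.write(f"{d}\t{names.get(d, d)}\t{r}\t{names.get(r, r)}\t\t\tno\tyes\n")


def write_robustness(prefix: str | Path, report: RobustnessReport) -> None:
    """TSV per replicate plus a JSON summary, under ``prefix``.tsv/.json."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".tsv"), "w") as fh:
        fh.write("replicate\talgorithm\trecovery\n")
        for alg, rates in sorted(report.per_replicate.items()):
            for i, rate in enumerate(rates):
                fh.write(f"{i}\t{alg}\t{rate:.6f}\n")
    prefix.with_suffix(".json").write_text(report.to_json() + "\n")


def write_distances(prefix: str | Path, report: IndicationDistanceReport) -> None:
    """TSV per pair plus a JSON summary, under ``prefix``.tsv/.json."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".tsv"), "w") as fh:
        fh.write("disease_id\tdrug_id\tdistance\n")
        for (d, r), v in sorted(report.distances.items()):
            fh.write(f"{d}\t{r}\t{v if v is not None else 'NA'}\n")
    prefix.with_suffix(".json").write_text(report.to_json() + "\n")
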
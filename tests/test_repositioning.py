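import itertools

import networkx as nx
import numpy as np
import pytest

from hetrepo.cluster import ClusterSet
from hetrepo.corpus import PpiGraph
from hetrepo.reposition import (
    CandidateSet,
    consensus,
    extract_candidates,
    indication_distances,
    recovery_rate,
    robustness,
)

from oracles import all_pairs_distances_fw

TYPES = {
    "D1": "disease",
    "D2": "disease",
    "R1": "drug",
    "R2": "drug",
    "R3": "drug",
}


def _cs(*clusters, algorithm="louvain"):
    return ClusterSet(algorithm, [frozenset(c) for c in clusters])


def _cands(*pairs):
    return CandidateSet(pairs=frozenset(pairs))


class TestExtractCandidates:
    def test_cross_product_minus_known(self):
        cand = extract_candidates(_cs({"D1", "D2", "R1"}), TYPES, known={("D1", "R1")})
        assert cand.pairs == frozenset({("D2", "R1")})
        assert cand.known_recovered == frozenset({("D1", "R1")})

    def test_overlapping_clusters_merge_provenance(self):
        cand = extract_candidates(_cs({"D1", "R2"}, {"D1", "R2", "R3"}), TYPES)
        assert cand.pairs == frozenset({("D1", "R2"), ("D1", "R3")})
        assert len(cand.provenance[("D1", "R2")]) == 2

    def test_single_type_cluster_contributes_nothing(self):
        assert extract_candidates(_cs({"D1", "D2"}), TYPES).pairs == frozenset()

    def test_equals_per_cluster_cross_product_bruteforce(self, bundle):
        """Candidate extraction equals the brute-force cluster-by-cluster
        cross product on the planted fixture."""
        from hetrepo.cluster import clusterone

        cs = clusterone(bundle.net)
        types = bundle.net.node_types
        known = bundle.corpus.known_indications
        expected = set()
        for V in cs.clusters:
            ds = [n for n in V if types[n] == "disease"]
            rs = [n for n in V if types[n] == "drug"]
            if ds and rs:
                expected |= set(itertools.product(ds, rs))
        expected -= set(known)
        assert extract_candidates(cs, types, known).pairs == frozenset(expected)

    def test_candidates_never_contain_known_indications(self):
        with pytest.raises(ValueError):
            CandidateSet(
                pairs=frozenset({("D1", "R1")}), known_recovered=frozenset({("D1", "R1")})
            )


class TestConsensus:
    def test_intersection_with_flag(self):
        c = consensus(_cands(("D1", "R1"), ("D2", "R2")), _cands(("D2", "R2"), ("D1", "R3")))
        assert c.pairs == frozenset({("D2", "R2")})
        assert c.consensus == c.pairs

    def test_disjoint_sets_empty(self):
        assert consensus(_cands(("D1", "R1")), _cands(("D2", "R2"))).pairs == frozenset()

    def test_idempotent(self):
        a = _cands(("D1", "R1"), ("D2", "R2"))
        assert consensus(a, a).pairs == a.pairs


class TestRecoveryRate:
    def test_identity_and_disjoint(self):
        a = _cands(("D1", "R1"), ("D2", "R2"))
        assert recovery_rate(a, a) == 1.0
        assert recovery_rate(a, _cands(("D9", "R9"))) == 0.0

    def test_partial_recovery(self):
        orig = _cands(*[(f"D{i}", f"R{i}") for i in range(4)])
        pert = _cands(*([(f"D{i}", f"R{i}") for i in range(3)] + [(f"X{i}", f"Y{i}") for i in range(10)]))
        assert recovery_rate(orig, pert) == 0.75

    def test_empty_original_is_error(self):
        with pytest.raises(ValueError):
            recovery_rate(_cands(), _cands(("D1", "R1")))

    def test_monotone_in_overlap(self):
        orig = _cands(*[(f"D{i}", f"R{i}") for i in range(5)])
        rates = [
            recovery_rate(orig, _cands(*[(f"D{i}", f"R{i}") for i in range(j)]))
            for j in range(1, 6)
        ]
        assert rates == sorted(rates)


class TestRobustness:
    def test_exact_edge_removal_count_and_determinism(self, bundle):
        net, known = bundle.net, bundle.corpus.known_indications
        n_edges = net.graph.number_of_edges()
        report = robustness(net, known, fraction=0.1, reps=2, master_seed=5)
        assert report.n_edges_removed == int(0.1 * n_edges)
        again = robustness(net, known, fraction=0.1, reps=2, master_seed=5)
        assert report.to_json() == again.to_json()

    def test_invalid_parameters(self, bundle):
        with pytest.raises(ValueError):
            robustness(bundle.net, bundle.corpus.known_indications, fraction=0.0)
        with pytest.raises(ValueError):
            robustness(bundle.net, bundle.corpus.known_indications, reps=0)


def _ppi(*edges):
    es = frozenset(frozenset(e) for e in edges)
    return PpiGraph(edges=es, nodes=frozenset().union(*es))


class TestIndicationDistances:
    def test_path_graph_distance(self):
        ppi = _ppi(("g1", "g2"), ("g2", "g3"))
        rep = indication_distances(ppi, {("D1", "R1")}, {"D1": frozenset({"g1"})}, {"R1": frozenset({"g3"})})
        assert rep.distances[("D1", "R1")] == 2
        assert rep.mean == 2 and rep.median == 2

    def test_shared_gene_is_distance_zero(self):
        ppi = _ppi(("g1", "g2"))
        rep = indication_distances(ppi, {("D1", "R1")}, {"D1": frozenset({"gX"})}, {"R1": frozenset({"gX"})})
        assert rep.distances[("D1", "R1")] == 0

    def test_unreachable_pair_excluded_from_mean(self):
        ppi = _ppi(("g1", "g2"), ("g3", "g4"))
        known = {("D1", "R1"), ("D2", "R1")}
        rep = indication_distances(
            ppi,
            known,
            {"D1": frozenset({"g1"}), "D2": frozenset({"g1"})},
            {"R1": frozenset({"g2"})} | {},
        )
        assert rep.n_computed == 2  # both reach g2 here
        rep2 = indication_distances(
            ppi, {("D1", "R1")}, {"D1": frozenset({"g1"})}, {"R1": frozenset({"g3"})}
        )
        assert rep2.distances[("D1", "R1")] is None
        assert rep2.n_uncomputable == 1 and rep2.mean is None

    def test_empty_ppi_is_error(self):
        ppi = PpiGraph(edges=frozenset(), nodes=frozenset())
        with pytest.raises(ValueError):
            indication_distances(ppi, set(), {}, {})

    def test_min_over_gene_target_combinations(self):
        ppi = _ppi(("g1", "g2"), ("g2", "g3"), ("g3", "g4"))
        rep = indication_distances(
            ppi,
            {("D1", "R1")},
            {"D1": frozenset({"g1", "g3"})},
            {"R1": frozenset({"g4"})},
        )
        assert rep.distances[("D1", "R1")] == 1  # g3-g4, not g1-g4

    def test_bfs_matches_floyd_warshall_on_random_graphs(self):
        """Pair distances agree with a dense Floyd-Warshall oracle on random
        graphs of up to 30 nodes."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            g = nx.gnp_random_graph(int(rng.integers(5, 31)), 0.15, seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, {n: f"g{n}" for n in g.nodes})
            if g.number_of_edges() == 0:
                continue
            ppi = PpiGraph(
                edges=frozenset(frozenset(e) for e in g.edges),
                nodes=frozenset(g.nodes),
            )
            fw = all_pairs_distances_fw(g)
            nodes = sorted(g.nodes)
            known = set()
            dis, dru = {}, {}
            for i in range(0, len(nodes) - 1, 2):
                d, r = f"D{i}", f"R{i}"
                dis[d] = frozenset({nodes[i]})
                dru[r] = frozenset({nodes[i + 1]})
                known.add((d, r))
            rep = indication_distances(ppi, known, dis, dru)
            for (d, r), got in rep.distances.items():
                u = next(iter(dis[d]))
                v = next(iter(dru[r]))
                assert got == fw[(u, v)]
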
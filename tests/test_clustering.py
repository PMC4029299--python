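import math

import networkx as nx
import numpy as np
import pytest

from hetrepo.cluster import (
    ClusterSet,
    clusterone,
    cohesiveness,
    louvain,
    mixed_clusters,
    modularity,
    read_clusters,
    write_clusters,
)

from conftest import bridged_triangles, two_triangles
from oracles import (
    best_partition_exhaustive,
    cohesiveness_bruteforce,
    modularity_bruteforce,
    random_weighted_graph,
)


class TestModularity:
    def test_two_triangles_split(self):
        g = two_triangles()
        part = {"a": 0, "b": 0, "c": 0, "x": 1, "y": 1, "z": 1}
        assert modularity(g, part) == pytest.approx(0.5, abs=1e-12)

    def test_single_community_is_zero(self):
        g = random_weighted_graph(np.random.default_rng(0), 12)
        assert modularity(g, {n: 0 for n in g}) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_on_random_graphs(self):
        """Per-community-sum implementation equals the pairwise double-loop
        oracle on random weighted graphs and random partitions."""
        rng = np.random.default_rng(1)
        for _ in range(30):
            g = random_weighted_graph(rng, int(rng.integers(4, 21)))
            part = {n: int(rng.integers(0, 4)) for n in g}
            assert modularity(g, part) == pytest.approx(
                modularity_bruteforce(g, part), abs=1e-12
            )

    def test_empty_network_is_error(self):
        with pytest.raises(ValueError, match="empty network"):
            modularity(nx.Graph(), {})

    def test_uncovered_node_is_error(self):
        g = two_triangles()
        with pytest.raises(ValueError, match="cover"):
            modularity(g, {"a": 0})


class TestLouvain:
    def test_recovers_two_triangles_at_global_optimum(self):
        g = two_triangles()
        best_q, _ = best_partition_exhaustive(g)
        part = louvain(g, seed=0)
        assert part.q == pytest.approx(best_q, abs=1e-12) == pytest.approx(0.5)
        assert sorted(sorted(c) for c in part.communities()) == [
            ["a", "b", "c"],
            ["x", "y", "z"],
        ]

    def test_complete_graph_stays_one_community(self):
        k4 = nx.complete_graph(4)
        best_q, blocks = best_partition_exhaustive(k4)
        assert best_q <= 1e-12  # no split beats the trivial partition
        assert len(louvain(k4, seed=3).communities()) == 1

    def test_deterministic_under_fixed_seed(self):
        g = random_weighted_graph(np.random.default_rng(5), 30, p=0.2)
        a = louvain(g, seed=11)
        b = louvain(g, seed=11)
        assert a.membership == b.membership and a.q == b.q

    def test_reported_q_equals_recomputed_modularity(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            g = random_weighted_graph(rng, 25, p=0.15)
            part = louvain(g, seed=2)
            assert part.q == pytest.approx(modularity(g, part.membership), abs=1e-12)

    def test_q_nondecreasing_across_levels_and_beats_singletons(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            g = random_weighted_graph(rng, 30, p=0.15)
            part = louvain(g, seed=4)
            qs = [q for _, q in part.levels]
            assert all(b >= a - 1e-10 for a, b in zip(qs, qs[1:]))
            singleton_q = modularity(g, {n: i for i, n in enumerate(g)})
            assert part.q >= singleton_q - 1e-12

    def test_close_to_independent_reference_optimiser(self):
        """Attained modularity is within a small margin of the networkx
        Louvain reference on random weighted graphs."""
        rng = np.random.default_rng(21)
        for trial in range(3):
            g = random_weighted_graph(rng, 40, p=0.1)
            ref = nx.community.louvain_communities(g, weight="weight", seed=7)
            ref_q = nx.community.modularity(g, ref, weight="weight")
            assert louvain(g, seed=trial).q >= ref_q - 0.05

    def test_empty_network_is_error(self):
        with pytest.raises(ValueError):
            louvain(nx.Graph(), seed=0)


class TestCohesiveness:
    def test_isolated_triangle_is_fully_cohesive(self):
        g = two_triangles()
        cc = cohesiveness(g, {"a", "b", "c"}, penalty_per_node=0)
        assert (cc.w_in, cc.w_bound, cc.f) == (3.0, 0.0, 1.0)

    def test_one_external_edge_drops_f_to_three_quarters(self):
        g = bridged_triangles()
        cc = cohesiveness(g, {"a", "b", "c"}, penalty_per_node=0)
        assert cc.f == pytest.approx(0.75)

    def test_large_penalty_drives_f_to_zero(self):
        g = two_triangles()
        f = cohesiveness(g, {"a", "b", "c"}, penalty_per_node=1e9).f
        assert f == pytest.approx(0.0, abs=1e-8)

    def test_unknown_node_is_error(self):
        with pytest.raises(ValueError, match="unknown"):
            cohesiveness(two_triangles(), {"a", "nope"}, 0)

    def test_matches_direct_summation_on_random_subsets(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            g = random_weighted_graph(rng, int(rng.integers(5, 25)))
            nodes = list(g.nodes)
            size = int(rng.integers(1, len(nodes) + 1))
            V = set(rng.choice(nodes, size=size, replace=False).tolist())
            pen = float(rng.uniform(0, 3))
            assert cohesiveness(g, V, pen).f == pytest.approx(
                cohesiveness_bruteforce(g, V, pen), abs=1e-12
            )


def _locally_optimal(g, V, penalty, tol=1e-9):
    f = cohesiveness(g, V, penalty).f
    boundary = {v for u in V for v in g[u] if v not in V}
    for v in sorted(boundary, key=str):
        if cohesiveness(g, V | {v}, penalty).f > f + tol:
            return False
    if len(V) > 1:
        for v in sorted(V, key=str):
            if cohesiveness(g, V - {v}, penalty).f > f + tol:
                return False
    return True


class TestClusterone:
    def test_bridged_triangles_split_into_two_clusters(self):
        cs = clusterone(bridged_triangles(), penalty_per_node=0, alpha=1.0)
        assert sorted(sorted(c) for c in cs.clusters) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_clique_returned_whole(self):
        cs = clusterone(nx.complete_graph(5), penalty_per_node=0)
        assert cs.clusters == [frozenset(range(5))]
        assert cs.meta[0]["pvalue"] == 0.0  # no boundary edges

    def test_deterministic(self):
        g = random_weighted_graph(np.random.default_rng(8), 30, p=0.2)
        a = clusterone(g, seed=0)
        b = clusterone(g, seed=0)
        assert a.clusters == b.clusters and a.meta == b.meta

    def test_every_cluster_is_one_step_locally_optimal(self):
        """No single boundary addition or member removal strictly increases
        f(V) for any returned cluster (exhaustive check, graphs <= 30
        nodes)."""
        rng = np.random.default_rng(17)
        graphs = [bridged_triangles(), two_triangles()] + [
            random_weighted_graph(rng, 25, p=0.2) for _ in range(3)
        ]
        for g in graphs:
            cs = clusterone(g, penalty_per_node=2.0, alpha=1.0, min_density=0.0, min_size=1)
            assert cs.clusters, "expected at least one cluster"
            for V in cs.clusters:
                assert _locally_optimal(g, set(V), 2.0)

    def test_min_size_filter(self):
        g = bridged_triangles()
        cs = clusterone(g, penalty_per_node=0, min_size=4, alpha=1.0)
        assert cs.clusters == []

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            clusterone(two_triangles(), min_size=0)
        with pytest.raises(ValueError):
            clusterone(two_triangles(), penalty_per_node=-1)


class TestMixedClusters:
    TYPES = {"D1": "disease", "D2": "disease", "D3": "disease", "R1": "drug", "R2": "drug", "R3": "drug"}

    def _cs(self, *clusters):
        return ClusterSet("clusterone", [frozenset(c) for c in clusters])

    def test_keeps_exactly_clusters_with_both_types(self):
        cs = self._cs({"D1", "D2"}, {"D3", "R1"}, {"R2", "R3"})
        kept = mixed_clusters(cs, self.TYPES)
        assert kept.clusters == [frozenset({"D3", "R1"})]

    def test_empty_input_stays_empty(self):
        assert mixed_clusters(self._cs(), self.TYPES).clusters == []

    def test_all_mixed_is_identity(self):
        cs = self._cs({"D1", "R1"}, {"D2", "R2", "R3"})
        assert mixed_clusters(cs, self.TYPES).clusters == cs.clusters


def test_cluster_tsv_round_trip(tmp_path):
    cs = ClusterSet("louvain", [frozenset({"D1", "R1"}), frozenset({"D2"})])
    types = {"D1": "disease", "D2": "disease", "R1": "drug"}
    write_clusters(tmp_path / "c.tsv", cs, types)
    loaded = read_clusters(tmp_path / "c.tsv")
    assert loaded.clusters == cs.clusters and loaded.algorithm == "louvain"
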
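import math

import numpy as np
import pytest

from mitochapnet import (Partition, WeightedBipartiteNetwork, WeightMatrix,
                         build_network, detect_communities,
                         exhaustive_partition_search, map_equation)
from mitochapnet.community import module_names
from mitochapnet.core import DataError

from conftest import small_random_nets


class TestBuildNetwork:
    def test_direct_construction(self):
        wm = WeightMatrix(["c0", "c1"], ["g0", "g1"],
                          np.array([[0.5, 0.0], [0.0, 0.7]]))
        net = build_network(wm)
        assert len(net.edges) == 2
        assert net.dropped_nodes == []

    def test_zero_degree_client_dropped(self):
        wm = WeightMatrix(["c0", "c1"], ["g0", "g1", "g2"],
                          np.array([[0.5, 0.0, 0.2], [0.3, 0.0, 0.9]]))
        net = build_network(wm)
        assert net.dropped_nodes == ["g1"]
        assert "g1" not in net.client_nodes

    def test_empty_network_error(self):
        wm = WeightMatrix(["c0"], ["g0"], np.zeros((1, 1)))
        with pytest.raises(DataError, match="empty network"):
            build_network(wm)

    def test_block_diagonal_components(self):
        from mitochapnet import generate_planted_network
        import networkx as nx
        wm, _ = generate_planted_network(4, 8, 4, 0.5, 0.0, 1.0, 0.0, seed=0)
        net = build_network(wm)
        g = nx.Graph()
        g.add_weighted_edges_from(net.edges)
        assert nx.number_connected_components(g) == 4


class TestMapEquation:
    def test_single_module_is_entropy_of_visit_rates(self, two_triangles):
        part = Partition({n: 1 for n in two_triangles.nodes}, 1)
        score = map_equation(two_triangles, part)
        assert score.L == pytest.approx(math.log2(6), abs=1e-12)
        # whole-graph module has exit rate 0
        assert score.per_module[0][2] == 0.0

    def test_two_triangles_component_partition(self, two_triangles):
        part = Partition({"a": 1, "x": 1, "y": 1, "b": 2, "u": 2, "v": 2}, 2)
        score = map_equation(two_triangles, part)
        assert score.L == pytest.approx(math.log2(3), abs=1e-12)
        for _, visit, exit_rate in score.per_module:
            assert exit_rate == 0.0
            assert visit == pytest.approx(0.5)

    def test_visit_rates_sum_to_one(self, two_triangles, complete_bipartite_2x2):
        for net in (two_triangles, complete_bipartite_2x2):
            part = Partition({n: 1 for n in net.nodes}, 1)
            score = map_equation(net, part)
            assert sum(v for _, v, _ in score.per_module) == pytest.approx(1.0)

    def test_weight_scale_invariance(self, two_triangles):
        part = Partition({"a": 1, "x": 1, "y": 1, "b": 2, "u": 2, "v": 2}, 2)
        L1 = map_equation(two_triangles, part).L
        scaled = WeightedBipartiteNetwork(
            two_triangles.chaperone_nodes, two_triangles.client_nodes,
            [(u, v, 2.0 * w) for u, v, w in two_triangles.edges], [])
        assert map_equation(scaled, part).L == pytest.approx(L1, abs=1e-14)

    def test_node_relabel_invariance(self, two_triangles):
        part = Partition({"a": 1, "x": 1, "y": 1, "b": 2, "u": 2, "v": 2}, 2)
        L1 = map_equation(two_triangles, part).L
        renamed = WeightedBipartiteNetwork(
            ["n_a", "n_b"], ["n_x", "n_y", "n_u", "n_v"],
            [(f"n_{u}", f"n_{v}", w) for u, v, w in two_triangles.edges], [])
        part2 = Partition({f"n_{k}": v for k, v in part.assignment.items()}, 2)
        assert map_equation(renamed, part2).L == pytest.approx(L1, abs=1e-14)

    def test_missing_node_error(self, two_triangles):
        part = Partition({"a": 1}, 1)
        with pytest.raises(DataError, match="missing"):
            map_equation(two_triangles, part)


class TestDetectCommunities:
    def test_two_triangles_recovers_components(self, two_triangles):
        part, score = detect_communities(two_triangles, n_restarts=4, seed=0)
        assert part.n_modules == 2
        assert score.L == pytest.approx(math.log2(3), abs=1e-12)
        assert part.assignment["a"] == part.assignment["x"] == part.assignment["y"]
        assert part.assignment["b"] == part.assignment["u"] == part.assignment["v"]

    def test_complete_bipartite_single_module(self, complete_bipartite_2x2):
        part, score = detect_communities(complete_bipartite_2x2, n_restarts=4, seed=0)
        oracle_part, oracle_score = exhaustive_partition_search(complete_bipartite_2x2)
        assert oracle_part.n_modules == 1  # no split lowers L
        assert part.n_modules == 1
        assert score.L == pytest.approx(oracle_score.L, abs=1e-12)

    def test_planted_recovers_three_modules(self, planted_net_strong):
        net, _ = planted_net_strong
        part, _ = detect_communities(net, n_restarts=8, seed=1)
        assert part.n_modules == 3

    def test_deterministic_given_seed(self, planted_net_strong):
        net, _ = planted_net_strong
        p1, s1 = detect_communities(net, n_restarts=4, seed=123)
        p2, s2 = detect_communities(net, n_restarts=4, seed=123)
        assert p1.assignment == p2.assignment
        assert s1.L == s2.L

    def test_never_above_trivial_baselines(self):
        for net in small_random_nets(n_nets=6):
            _, score = detect_communities(net, n_restarts=4, seed=0)
            single = map_equation(net, Partition({n: 1 for n in net.nodes}, 1)).L
            singletons = map_equation(
                net, Partition({n: i + 1 for i, n in enumerate(net.nodes)},
                               net.n_nodes)).L
            assert score.L <= single + 1e-12
            assert score.L <= singletons + 1e-12

    def test_labels_contiguous_from_one(self, planted_net_strong):
        net, _ = planted_net_strong
        part, _ = detect_communities(net, n_restarts=2, seed=0)
        labels = set(part.assignment.values())
        assert labels == set(range(1, part.n_modules + 1))

    def test_errors(self, two_triangles):
        with pytest.raises(DataError):
            detect_communities(two_triangles, n_restarts=0, seed=0)


class TestExhaustiveOracle:
    def test_single_edge(self, single_edge_net):
        part, score = exhaustive_partition_search(single_edge_net)
        # single module beats the 2-singleton split for one edge
        single = map_equation(single_edge_net,
                              Partition({n: 1 for n in single_edge_net.nodes}, 1)).L
        assert score.L == pytest.approx(single, abs=1e-14)
        assert part.n_modules == 1

    def test_two_triangles_global_minimum(self, two_triangles):
        part, score = exhaustive_partition_search(two_triangles)
        assert part.n_modules == 2
        assert score.L == pytest.approx(math.log2(3), abs=1e-12)

    def test_greedy_matches_oracle_on_small_nets(self):
        for net in small_random_nets(n_nets=8):
            _, greedy = detect_communities(net, n_restarts=8, seed=3)
            _, oracle = exhaustive_partition_search(net)
            assert oracle.L <= greedy.L + 1e-12
            assert greedy.L - oracle.L < 1e-12

    def test_too_many_nodes_error(self, planted_net_strong):
        net, _ = planted_net_strong
        with pytest.raises(DataError, match="exceeds"):
            exhaustive_partition_search(net, max_nodes=10)


class TestModuleNames:
    def test_highest_degree_chaperone_names_module(self, two_triangles):
        part = Partition({"a": 1, "x": 1, "y": 1, "b": 2, "u": 2, "v": 2}, 2)
        names = module_names(two_triangles, part)
        assert names == {1: "a", 2: "b"}


class TestExports:
    def test_edgelist_and_attributes_roundtrip(self, tmp_path, two_triangles):
        from mitochapnet.community import write_edgelist, write_node_attributes
        part, _ = detect_communities(two_triangles, n_restarts=2, seed=0)
        write_edgelist(two_triangles, tmp_path / "edges.tsv")
        write_node_attributes(two_triangles, part, tmp_path / "nodes.tsv")
        import pandas as pd
        edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert list(edges.columns) == ["source", "target", "weight"]
        assert len(edges) == 6
        nodes = pd.read_csv(tmp_path / "nodes.tsv", sep="\t")
        assert set(nodes["type"]) == {"chaperone", "client"}
        assert len(nodes) == 6
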
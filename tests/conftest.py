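import numpy as np
import pytest

from mitochapnet import (WeightedBipartiteNetwork, build_network,
                         generate_planted_network)


@pytest.fixture(scope="session")
def two_triangles():
    """Two disjoint triangles, all edge weights 1 (6 nodes, 6 edges)."""
    edges = [("a", "x", 1.0), ("a", "y", 1.0), ("x", "y", 1.0),
             ("b", "u", 1.0), ("b", "v", 1.0), ("u", "v", 1.0)]
    return WeightedBipartiteNetwork(chaperone_nodes=["a", "b"],
                                    client_nodes=["x", "y", "u", "v"],
                                    edges=edges, dropped_nodes=[])


@pytest.fixture(scope="session")
def complete_bipartite_2x2():
    edges = [("c1", "g1", 1.0), ("c1", "g2", 1.0),
             ("c2", "g1", 1.0), ("c2", "g2", 1.0)]
    return WeightedBipartiteNetwork(["c1", "c2"], ["g1", "g2"], edges, [])


@pytest.fixture(scope="session")
def single_edge_net():
    return WeightedBipartiteNetwork(["c1"], ["g1"], [("c1", "g1", 0.7)], [])


@pytest.fixture(scope="session")
def planted_net_strong():
    """The planted K=3 strong-separation network used throughout."""
    wm, truth = generate_planted_network(15, 90, 3, w_in=0.6, w_out=0.05,
                                         edge_prob_in=0.9, edge_prob_out=0.1,
                                         seed=1)
    return build_network(wm), truth


@pytest.fixture(scope="session")
def small_modular_bipartite():
    """Small strictly bipartite net with two planted modules (4 x 12)."""
    wm, truth = generate_planted_network(4, 12, 2, w_in=0.6, w_out=0.05,
                                         edge_prob_in=1.0, edge_prob_out=0.1,
                                         seed=5)
    return build_network(wm)


def small_random_nets(n_nets=5, max_nodes=8):
    """Random weighted bipartite nets with <= max_nodes nodes (oracle fixtures)."""
    nets = []
    rng = np.random.default_rng(42)
    for _ in range(n_nets):
        n_chap = int(rng.integers(2, 4))
        n_cli = int(rng.integers(2, max_nodes - n_chap + 1))
        while True:
            w = rng.random((n_chap, n_cli)) * (rng.random((n_chap, n_cli)) < 0.6)
            if (w.sum(axis=1) > 0).all() and (w.sum(axis=0) > 0).all():
                break
        chap = [f"c{i}" for i in range(n_chap)]
        cli = [f"g{j}" for j in range(n_cli)]
        edges = [(chap[i], cli[j], float(w[i, j]))
                 for i, j in zip(*np.nonzero(w))]
        nets.append(WeightedBipartiteNetwork(chap, cli, edges, []))
    return nets


def adjusted_rand_index(labels_a, labels_b):
    """ARI by the standard contingency-table formula (independent oracle)."""
    from math import comb

    a_vals = sorted(set(labels_a))
    b_vals = sorted(set(labels_b))
    table = np.zeros((len(a_vals), len(b_vals)), dtype=int)
    for x, y in zip(labels_a, labels_b):
        table[a_vals.index(x), b_vals.index(y)] += 1
    n = table.sum()
    sum_ij = sum(comb(int(v), 2) for v in table.ravel())
    sum_a = sum(comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in table.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
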
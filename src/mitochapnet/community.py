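"""Weighted bipartite network construction and map-equation community detection.

The bipartite chaperone-client graph is treated as an undirected weighted
graph for flow purposes.  Partition quality is the two-level map equation:
with node visit rates ``p_a = strength(a) / 2W`` and module exit rates
``q_i = cut(i) / 2W``,

    L = q * H(Q) + sum_i p_i_circ * H(P_i)

where ``q = sum_i q_i``, ``H(Q)`` is the base-2 entropy of ``{q_i / q}``,
``p_i_circ = q_i + sum_{a in i} p_a`` and ``H(P_i)`` the entropy of the
normalized vector ``(q_i, {p_a}_{a in i})``; ``0 log 0 = 0`` throughout.
Lower L means the partition compresses a random walk better.

The optimizer is a seeded greedy node-move search (random-order sweeps moving
each node to the neighboring module that most decreases L, followed by
module-merge attempts, iterated to convergence) with restarts, always
cross-checked against the single-module and all-singleton baselines.  An
exhaustive Bell-number enumeration is provided as an oracle for small graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import DataError, write_json

_CONVERGENCE_EPS = 1e-10  # bits; a full sweep improving less than this stops
_MOVE_EPS = 1e-13  # strict-improvement threshold for a single move


@dataclass
class WeightedBipartiteNetwork:
    chaperone_nodes: list[str]
    client_nodes: list[str]
    edges: list[tuple[str, str, float]]  # (chaperone, client, weight > 0)
    dropped_nodes: list[str]  # zero-degree genes excluded from the graph

    @property
    def nodes(self) -> list[str]:
        return self.chaperone_nodes + self.client_nodes

    @property
    def n_nodes(self) -> int:
        return len(self.chaperone_nodes) + len(self.client_nodes)


@dataclass
class Partition:
    assignment: dict[str, int]  # node -> module label, contiguous from 1
    n_modules: int


@dataclass
class PartitionScore:
    L: float  # description length in bits
    per_module: list[tuple[int, float, float]]  # (module, visit_rate, exit_rate)


def build_network(pc) -> WeightedBipartiteNetwork:
    """One undirected weighted edge per strictly positive matrix cell.

    ``pc`` is any object with ``chaperone_ids``, ``client_ids`` and a weight
    matrix ``w`` (``PanCancerMatrix`` or ``WeightMatrix``).  Zero-degree genes
    are recorded in ``dropped_nodes`` rather than added to the graph.  A gene
    present in both panels contributes a single node; its self-cell (always
    zero after filtering) is skipped defensively.
    """
    w = np.asarray(pc.w, dtype=float)
    chap_ids, cli_ids = list(pc.chaperone_ids), list(pc.client_ids)
    edges = []
    for i, j in zip(*np.nonzero(w > 0)):
        if chap_ids[i] == cli_ids[j]:
            continue
        edges.append((chap_ids[i], cli_ids[j], float(w[i, j])))
    if not edges:
        raise DataError("empty network: no strictly positive cell")
    deg: dict[str, int] = {}
    for u, v, _ in edges:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    chap_nodes = [g for g in chap_ids if g in deg]
    cli_nodes = [g for g in cli_ids if g in deg and g not in set(chap_nodes)]
    dropped = [g for g in chap_ids if g not in deg]
    dropped += [g for g in cli_ids if g not in deg and g not in set(dropped)]
    return WeightedBipartiteNetwork(chaperone_nodes=chap_nodes,
                                    client_nodes=cli_nodes,
                                    edges=edges, dropped_nodes=dropped)


# ---------------------------------------------------------------------------
# internal flat graph representation

class _Graph:
    """Index-based view of a network for fast scoring and search."""

    def __init__(self, net: WeightedBipartiteNetwork):
        self.names = net.nodes
        index = {g: i for i, g in enumerate(self.names)}
        n = len(self.names)
        eu = np.array([index[u] for u, _, _ in net.edges], dtype=np.int64)
        ev = np.array([index[v] for _, v, _ in net.edges], dtype=np.int64)
        ew = np.array([w for _, _, w in net.edges], dtype=float)
        if np.any(ew <= 0):
            raise DataError("edge weights must be strictly positive")
        self.eu, self.ev, self.ew = eu, ev, ew
        self.n = n
        strength = np.bincount(eu, weights=ew, minlength=n)
        strength += np.bincount(ev, weights=ew, minlength=n)
        self.two_w = float(ew.sum() * 2.0)
        self.p = strength / self.two_w  # node visit rates; sum to 1
        # adjacency lists (neighbor index, normalized weight)
        nbr: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for u, v, w in zip(eu, ev, ew / self.two_w):
            nbr[u].append((int(v), float(w)))
            nbr[v].append((int(u), float(w)))
        self.nbr_idx = [np.array([i for i, _ in lst], dtype=np.int64) for lst in nbr]
        self.nbr_w = [np.array([w for _, w in lst], dtype=float) for lst in nbr]
        self.node_term = float(sum(_plogp(x) for x in self.p))

    def module_rates(self, labels: np.ndarray, n_mod: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-module (exit rate q_i, visit-rate sum p_i), normalized."""
        pn = np.bincount(labels, weights=self.p, minlength=n_mod)
        lu, lv = labels[self.eu], labels[self.ev]
        cross = lu != lv
        wn = self.ew / self.two_w
        qn = np.bincount(lu[cross], weights=wn[cross], minlength=n_mod)
        qn += np.bincount(lv[cross], weights=wn[cross], minlength=n_mod)
        return qn, pn

    def score(self, labels: np.ndarray) -> float:
        n_mod = int(labels.max()) + 1 if labels.size else 0
        qn, pn = self.module_rates(labels, n_mod)
        return _L_from_rates(qn, pn, self.node_term)


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0.0 else 0.0


def _L_from_rates(qn: np.ndarray, pn: np.ndarray, node_term: float) -> float:
    sum_q = float(qn.sum())
    s1 = float(sum(_plogp(q) for q in qn))
    s2 = float(sum(_plogp(q + p) for q, p in zip(qn, pn)))
    return _plogp(sum_q) - 2.0 * s1 + s2 - node_term


def _labels_from_partition(graph: _Graph, part: Partition) -> np.ndarray:
    labels = np.empty(graph.n, dtype=np.int64)
    for i, name in enumerate(graph.names):
        if name not in part.assignment:
            raise DataError(f"node {name!r} missing from partition")
        labels[i] = part.assignment[name] - 1
    return labels


def _canonical(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel modules contiguously from 0 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[int(lab)] = len(mapping)
        out[i] = mapping[int(lab)]
    return out, len(mapping)


def map_equation(net: WeightedBipartiteNetwork, part: Partition) -> PartitionScore:
    """Two-level map-equation description length of a partition, in bits."""
    graph = _Graph(net)
    labels = _labels_from_partition(graph, part)
    n_mod = int(labels.max()) + 1
    qn, pn = graph.module_rates(labels, n_mod)
    L = _L_from_rates(qn, pn, graph.node_term)
    per_module = [(m + 1, float(pn[m]), float(qn[m])) for m in range(n_mod)]
    return PartitionScore(L=L, per_module=per_module)


# ---------------------------------------------------------------------------
# greedy search

def _sweep(graph: _Graph, labels: np.ndarray, qn: np.ndarray, pn: np.ndarray,
           sum_q: float, L: float, rng: np.random.Generator,
           ) -> tuple[float, float]:
    """One random-order pass of single-node moves; mutates labels/qn/pn."""
    log2 = math.log2
    p_arr = graph.p
    order = rng.permutation(graph.n)
    for v in order:
        a = int(labels[v])
        p_v = p_arr[v]
        # weight from v to each adjacent module (normalized)
        w_to: dict[int, float] = {}
        for lab, w in zip(labels[graph.nbr_idx[v]], graph.nbr_w[v]):
            lab = int(lab)
            w_to[lab] = w_to.get(lab, 0.0) + w
        w_a = w_to.get(a, 0.0)
        qa, pa = qn[a], pn[a]
        qa_new = qa - p_v + 2.0 * w_a
        pa_new = pa - p_v
        if pa_new <= 1e-15:  # module emptied: clamp rates exactly
            qa_new = 0.0
            pa_new = 0.0
        delta_a = (-2.0 * (qa_new * log2(qa_new) if qa_new > 0.0 else 0.0)
                   + ((qa_new + pa_new) * log2(qa_new + pa_new)
                      if qa_new + pa_new > 0.0 else 0.0)
                   + 2.0 * (qa * log2(qa) if qa > 0.0 else 0.0)
                   - (qa + pa) * log2(qa + pa))
        sum_q_base = sum_q + qa_new - qa
        log_sum_q = sum_q * log2(sum_q) if sum_q > 0.0 else 0.0
        best_delta, best_b = 0.0, -1
        for b in sorted(w_to):
            if b == a:
                continue
            qb, pb = qn[b], pn[b]
            qb_new = qb + p_v - 2.0 * w_to[b]
            pb_new = pb + p_v
            sum_q_new = sum_q_base + qb_new - qb
            delta = ((sum_q_new * log2(sum_q_new) if sum_q_new > 0.0 else 0.0)
                     - log_sum_q + delta_a
                     - 2.0 * (qb_new * log2(qb_new) if qb_new > 0.0 else 0.0)
                     + (qb_new + pb_new) * log2(qb_new + pb_new)
                     + 2.0 * (qb * log2(qb) if qb > 0.0 else 0.0)
                     - ((qb + pb) * log2(qb + pb) if qb + pb > 0.0 else 0.0))
            if delta < best_delta - _MOVE_EPS:
                best_delta, best_b = delta, b
        if best_b >= 0:
            b = best_b
            sum_q = sum_q_base + p_v - 2.0 * w_to[b]
            qn[a], pn[a] = qa_new, pa_new
            qn[b] += p_v - 2.0 * w_to[b]
            pn[b] += p_v
            labels[v] = b
            L += best_delta
    return sum_q, L


def _merge_pass(graph: _Graph, labels: np.ndarray, qn: np.ndarray,
                pn: np.ndarray, sum_q: float, L: float) -> tuple[float, float, bool]:
    """Greedily merge edge-connected module pairs while any merge lowers L."""
    wn = graph.ew / graph.two_w
    any_merge = False
    while True:
        lu, lv = labels[graph.eu], labels[graph.ev]
        between: dict[tuple[int, int], float] = {}
        for a, b, w in zip(lu, lv, wn):
            if a == b:
                continue
            key = (int(min(a, b)), int(max(a, b)))
            between[key] = between.get(key, 0.0) + w
        best = (0.0, None)
        for (a, b), w_ab in sorted(between.items()):
            q_new = qn[a] + qn[b] - 2.0 * w_ab
            p_new = pn[a] + pn[b]
            sum_q_new = sum_q - qn[a] - qn[b] + q_new
            delta = (_plogp(sum_q_new) - _plogp(sum_q)
                     - 2.0 * (_plogp(q_new) - _plogp(qn[a]) - _plogp(qn[b]))
                     + _plogp(q_new + p_new)
                     - _plogp(qn[a] + pn[a]) - _plogp(qn[b] + pn[b]))
            if delta < best[0] - _MOVE_EPS:
                best = (delta, (a, b, w_ab))
        if best[1] is None:
            return sum_q, L, any_merge
        delta, (a, b, w_ab) = best
        labels[labels == b] = a
        sum_q += -2.0 * w_ab
        qn[a] += qn[b] - 2.0 * w_ab
        pn[a] += pn[b]
        qn[b] = pn[b] = 0.0
        L += delta
        any_merge = True


def _greedy_once(graph: _Graph, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    labels = np.arange(graph.n, dtype=np.int64)  # all singletons
    n_mod = graph.n
    qn, pn = graph.module_rates(labels, n_mod)
    sum_q = float(qn.sum())
    L = _L_from_rates(qn, pn, graph.node_term)
    while True:
        L_before = L
        while True:
            L_sweep = L
            sum_q, L = _sweep(graph, labels, qn, pn, sum_q, L, rng)
            if L_sweep - L < _CONVERGENCE_EPS:
                break
        sum_q, L, merged = _merge_pass(graph, labels, qn, pn, sum_q, L)
        if not merged and L_before - L < _CONVERGENCE_EPS:
            break
    labels, _ = _canonical(labels)
    return labels, graph.score(labels)  # rescore from scratch to shed drift


def detect_communities(net: WeightedBipartiteNetwork, n_restarts: int = 8,
                       seed: int | np.random.SeedSequence = 0,
                       ) -> tuple[Partition, PartitionScore]:
    """Best-of-restarts greedy minimization of the map equation.

    The returned L is additionally guaranteed not to exceed the single-module
    or all-singleton baselines, which are evaluated explicitly.  Deterministic
    for a given (network, n_restarts, seed).
    """
    if n_restarts < 1:
        raise DataError("n_restarts must be >= 1")
    graph = _Graph(net)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    best_labels, best_L = None, math.inf
    for child in ss.spawn(n_restarts):
        labels, L = _greedy_once(graph, np.random.default_rng(child))
        if L < best_L - _MOVE_EPS:
            best_labels, best_L = labels, L
    # explicit baseline candidates
    for cand in (np.zeros(graph.n, dtype=np.int64), np.arange(graph.n, dtype=np.int64)):
        L = graph.score(cand)
        if L < best_L - _MOVE_EPS:
            best_labels, best_L = cand, L
    labels, n_mod = _canonical(best_labels)
    part = Partition(assignment={name: int(lab) + 1 for name, lab
                                 in zip(graph.names, labels)},
                     n_modules=n_mod)
    return part, map_equation(net, part)


def exhaustive_partition_search(net: WeightedBipartiteNetwork, max_nodes: int = 10,
                                ) -> tuple[Partition, PartitionScore]:
    """Global minimum of L over all set partitions (test oracle).

    Enumerates restricted-growth strings (Bell-number enumeration); ties are
    broken by fewer modules, then lexicographically smaller assignment.
    """
    graph = _Graph(net)
    if graph.n > max_nodes:
        raise DataError(f"{graph.n} nodes exceeds max_nodes={max_nodes}")

    best: tuple[float, int, tuple[int, ...]] | None = None

    def recurse(prefix: list[int], n_used: int) -> None:
        nonlocal best
        if len(prefix) == graph.n:
            labels = np.array(prefix, dtype=np.int64)
            L = graph.score(labels)
            key = (L, n_used, tuple(prefix))
            if best is None or key[0] < best[0] - 1e-15 or (
                    abs(key[0] - best[0]) <= 1e-15 and key[1:] < best[1:]):
                best = key
            return
        for lab in range(n_used + 1):
            recurse(prefix + [lab], max(n_used, lab + 1))

    recurse([], 0)
    labels = np.array(best[2], dtype=np.int64)
    part = Partition(assignment={name: int(lab) + 1 for name, lab
                                 in zip(graph.names, labels)},
                     n_modules=int(labels.max()) + 1)
    return part, map_equation(net, part)


def module_names(net: WeightedBipartiteNetwork, part: Partition) -> dict[int, str]:
    """Name each module after its highest-degree chaperone (ties: lexicographic)."""
    degree: dict[str, int] = {}
    for u, v, _ in net.edges:
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
    names: dict[int, str] = {}
    for m in range(1, part.n_modules + 1):
        chaps = [g for g in net.chaperone_nodes if part.assignment[g] == m]
        if chaps:
            names[m] = sorted(chaps, key=lambda g: (-degree.get(g, 0), g))[0]
        else:
            names[m] = f"module{m}"
    return names


def write_edgelist(net: WeightedBipartiteNetwork, path: str | Path) -> None:
    """Cytoscape-importable weighted edge list (source, target, weight)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in net.edges:
            fh.write(f"{u}\t{v}\t{w:.17g}\n")


def write_node_attributes(net: WeightedBipartiteNetwork, part: Partition,
                          path: str | Path) -> None:
    degree: dict[str, int] = {}
    for u, v, _ in net.edges:
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
    with open(path, "w") as fh:
        fh.write("node\ttype\tmodule\tdegree\n")
        for g in net.chaperone_nodes:
            fh.write(f"{g}\tchaperone\t{part.assignment[g]}\t{degree[g]}\n")
        for g in net.client_nodes:
            fh.write(f"{g}\tclient\t{part.assignment[g]}\t{degree[g]}\n")


def write_partition_json(part: Partition, score: PartitionScore,
                         path: str | Path, names: dict[int, str] | None = None) -> None:
    obj = {
        "assignment": part.assignment,
        "n_modules": part.n_modules,
        "L_bits": score.L,
        "per_module": [{"module": m, "visit_rate": p, "exit_rate": q}
                       for m, p, q in score.per_module],
    }
    if names:
        obj["module_names"] = {str(k): v for k, v in names.items()}
    write_json(obj, path)
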
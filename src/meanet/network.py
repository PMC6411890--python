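"""Synchrony-weighted electrode graphs, modularity, and Louvain communities.

Electrodes are nodes; each pair of active electrodes carries an
undirected edge weighted by its synchrony value, except that weak links
(synchrony below 0.10 by default) are dropped — a deliberately permissive
filter that keeps the graph near-clique and leaves structure discovery
to modularity maximization.

Modularity of a partition is

    Q = sum_c [ W_in_c / (2m) - (K_c / (2m))^2 ]

with W_in_c the within-community weight (each unordered pair counted
twice), K_c the summed node strengths, and m the total edge weight;
equivalently Q = (1/2m) * sum_ij (A_ij - k_i k_j / 2m) * delta(c_i, c_j).
Q = 0 for the all-in-one partition on any graph.

Louvain maximization is implemented here directly so that tie-breaking
(lowest community label) and the node visiting order (seeded
permutation) are fully deterministic under a fixed seed; the library
implementations in networkx serve as an independent cross-check in the
test suite.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from meanet.config import DataError, NetworkConfig
from meanet.containers import Partition, SynchronyMatrix

_EPS = 1e-12


def build_graph(sync: SynchronyMatrix, threshold: float = 0.10) -> nx.Graph:
    """Weighted electrode graph with weak edges removed.

    An edge (i, j) is retained iff synchrony >= threshold (links strictly
    below the threshold are filtered out); electrodes whose every link is
    filtered remain as isolated nodes.
    """
    vals = sync.values
    if not np.allclose(vals, vals.T):
        raise DataError("synchrony matrix must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(sync.electrode_ids)
    n = len(sync.electrode_ids)
    for a in range(n):
        for b in range(a + 1, n):
            w = float(vals[a, b])
            if w >= threshold:
                g.add_edge(sync.electrode_ids[a], sync.electrode_ids[b],
                           weight=w)
    return g


def modularity(graph: nx.Graph, labels: dict, resolution: float = 1.0) -> float:
    """Modularity Q of a labelled partition of a weighted graph."""
    m = graph.size(weight="weight")
    if m <= 0:
        raise DataError("modularity undefined on a graph with no edge weight")
    degrees = dict(graph.degree(weight="weight"))
    w_in: dict = {}
    k_c: dict = {}
    for node, k in degrees.items():
        c = labels[node]
        k_c[c] = k_c.get(c, 0.0) + k
    for u, v, w in graph.edges(data="weight", default=1.0):
        if labels[u] == labels[v]:
            # each unordered pair counted twice; self-loops once by nx degree
            w_in[labels[u]] = w_in.get(labels[u], 0.0) + (2.0 * w if u != v else w)
    two_m = 2.0 * m
    q = 0.0
    for c, k in k_c.items():
        q += w_in.get(c, 0.0) / two_m - resolution * (k / two_m) ** 2
    return q


def _one_level(adj: dict[int, dict[int, float]], k: dict[int, float],
               two_m: float, order: list[int], resolution: float,
               ) -> dict[int, int]:
    """Louvain phase 1: greedy single-node moves until no move improves Q.

    ``adj`` maps node -> {neighbor: weight} with self-loops stored as the
    full ordered internal weight. Moves go to the neighboring community
    with the largest positive modularity gain, ties broken by lowest
    community label.
    """
    community = {u: u for u in adj}
    sigma_tot = {u: k[u] for u in adj}
    improved = True
    while improved:
        improved = False
        for u in order:
            c_u = community[u]
            # weights from u to each neighboring community (excluding self-loop)
            w_to: dict[int, float] = {}
            for v, w in adj[u].items():
                if v != u:
                    w_to[community[v]] = w_to.get(community[v], 0.0) + w
            sigma_tot[c_u] -= k[u]
            best_c, best_gain = c_u, w_to.get(c_u, 0.0) - \
                resolution * sigma_tot[c_u] * k[u] / two_m
            for c in sorted(w_to):
                if c == c_u:
                    continue
                gain = w_to[c] - resolution * sigma_tot[c] * k[u] / two_m
                if gain > best_gain + _EPS or \
                        (abs(gain - best_gain) <= _EPS and c < best_c):
                    best_c, best_gain = c, gain
            sigma_tot[best_c] = sigma_tot.get(best_c, 0.0) + k[u]
            if best_c != c_u:
                community[u] = best_c
                improved = True
    return community


def _aggregate(adj: dict[int, dict[int, float]], community: dict[int, int],
               ) -> dict[int, dict[int, float]]:
    """Louvain phase 2: communities become super-nodes with self-loops."""
    new_adj: dict[int, dict[int, float]] = {}
    for u, nbrs in adj.items():
        cu = community[u]
        row = new_adj.setdefault(cu, {})
        for v, w in nbrs.items():
            cv = community[v]
            row[cv] = row.get(cv, 0.0) + w
    return new_adj


def louvain(graph: nx.Graph, seed: int = 0, resolution: float = 1.0,
            restarts: int = 1) -> Partition:
    """Louvain modularity maximization with deterministic tie-breaking.

    Phase 1 repeatedly moves single nodes to the neighboring community
    with the largest positive gain (ties to the lowest label); phase 2
    aggregates communities into super-nodes and repeats; the algorithm
    stops when a full level no longer improves Q. The node visiting
    order is a seeded permutation, so a fixed seed gives a fixed
    partition. With ``restarts`` > 1 the best-Q partition over restarts
    (with distinct sub-seeds) is returned.
    """
    if graph.number_of_nodes() == 0:
        raise DataError("empty graph")
    if graph.size(weight="weight") <= 0:
        raise DataError("graph has no edge weight (m = 0)")
    best: Partition | None = None
    for r in range(restarts):
        part = _louvain_single(graph, seed=seed + r, resolution=resolution)
        if best is None or part.modularity_q > best.modularity_q:
            best = part
    return best


def _louvain_single(graph: nx.Graph, seed: int, resolution: float) -> Partition:
    nodes = sorted(graph.nodes)
    adj: dict[int, dict[int, float]] = {u: {} for u in nodes}
    for u, v, w in graph.edges(data="weight", default=1.0):
        if u == v:
            adj[u][u] = adj[u].get(u, 0.0) + 2.0 * w
        else:
            adj[u][v] = adj[u].get(v, 0.0) + w
            adj[v][u] = adj[v].get(u, 0.0) + w
    rng = np.random.default_rng(seed)

    # flat assignment of original nodes, refined level by level
    flat = {u: u for u in nodes}
    while True:
        k = {u: sum(nbrs.values()) for u, nbrs in adj.items()}
        two_m = sum(k.values())
        order = [list(adj)[i] for i in rng.permutation(len(adj))]
        community = _one_level(adj, k, two_m, order, resolution)
        if all(community[u] == u for u in adj) or \
                len(set(community.values())) == len(adj):
            break
        flat = {orig: community[c] for orig, c in flat.items()}
        adj = _aggregate(adj, community)
        if len(adj) == 1:
            break

    # relabel communities 0..k-1 by smallest member electrode id
    groups: dict[int, list[int]] = {}
    for u, c in flat.items():
        groups.setdefault(c, []).append(u)
    ordered = sorted(groups.values(), key=min)
    labels = {u: idx for idx, members in enumerate(ordered) for u in members}
    return Partition(labels=labels, modularity_q=modularity(
        graph, labels, resolution=resolution))


def count_communities(partition: Partition,
                      count_singletons: bool = False) -> int:
    """Number of detected communities.

    By default only communities with at least two members count;
    isolated electrodes form singleton communities, which are reported
    separately (``partition.n_singletons``).
    """
    if count_singletons:
        return partition.n_communities + partition.n_singletons
    return partition.n_communities


def brute_force_best_partition(graph: nx.Graph,
                               resolution: float = 1.0) -> Partition:
    """Exhaustive modularity maximization over all set partitions.

    Exponential (Bell-number) cost — usable only on tiny graphs; exists
    as the exact reference for the heuristic optimizer.
    """
    nodes = sorted(graph.nodes)
    if len(nodes) > 10:
        raise ValueError("brute force is limited to <= 10 nodes")
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    two_m = a.sum()
    k = a.sum(axis=1)
    # Q(labels) = sum over same-community (i, j), diagonal included, of
    # (A_ij - k_i k_j / 2m) / 2m
    b = (a - resolution * np.outer(k, k) / two_m) / two_m

    best_q, best_labels = -np.inf, None
    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for smaller in partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [[first] + block] + smaller[i + 1:]
            yield [[first]] + smaller

    for blocks in partitions(list(range(len(nodes)))):
        q = sum(b[np.ix_(blk, blk)].sum() for blk in blocks)
        if q > best_q:
            best_q = q
            best_labels = {nodes[u]: i for i, blk in enumerate(blocks)
                           for u in blk}
    return Partition(labels=best_labels, modularity_q=float(best_q))
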
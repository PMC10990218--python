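"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — exhaustive path enumeration, triple
loops, dynamic programming over all walks — and shares no code with the
package's computation paths.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

_REL_TOL = 1e-9


def naive_counts_weights(S: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of C[b, k] = sum_d S[b, d] * Q[d, k]."""
    nb, nd = S.shape
    _, k_count = Q.shape
    C = np.zeros((nb, k_count))
    for b in range(nb):
        for k in range(k_count):
            for d in range(nd):
                C[b, k] += S[b, d] * Q[d, k]
    return C


def _all_shortest_paths(G: nx.DiGraph, s, t, cost):
    """All minimum-cost simple paths s->t by exhaustive enumeration."""
    best, paths = np.inf, []
    for path in nx.all_simple_paths(G, s, t):
        c = sum(cost(u, v) for u, v in zip(path, path[1:]))
        if c < best * (1 - _REL_TOL):
            best, paths = c, [path]
        elif abs(c - best) <= _REL_TOL * max(best, 1.0):
            paths.append(path)
    return paths


def brute_betweenness(G: nx.DiGraph, weighted: bool = True):
    """Unnormalized node and edge betweenness via path enumeration."""
    if weighted:
        cost = lambda u, v: 1.0 / G[u][v]["weight"]
    else:
        cost = lambda u, v: 1.0
    node_btw = {n: 0.0 for n in G.nodes}
    edge_btw = {e: 0.0 for e in G.edges}
    for s, t in itertools.permutations(G.nodes, 2):
        paths = _all_shortest_paths(G, s, t, cost)
        if not paths:
            continue
        frac = 1.0 / len(paths)
        for path in paths:
            for v in path[1:-1]:
                node_btw[v] += frac
            for e in zip(path, path[1:]):
                edge_btw[e] += frac
    return node_btw, edge_btw


def power_iteration_pagerank(
    G: nx.DiGraph, alpha: float = 0.85, tol: float = 1e-12
) -> dict:
    """Weighted PageRank by explicit power iteration with dangling spread."""
    nodes = list(G.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    P = np.zeros((n, n))
    dangling = np.zeros(n, dtype=bool)
    for u in nodes:
        out = G.out_degree(u, weight="weight")
        if out > 0:
            for v in G.successors(u):
                P[idx[u], idx[v]] = G[u][v]["weight"] / out
        else:
            dangling[idx[u]] = True
    x = np.full(n, 1.0 / n)
    for _ in range(10_000):
        dangling_mass = x[dangling].sum()
        new = alpha * (x @ P + dangling_mass / n) + (1 - alpha) / n
        if np.abs(new - x).sum() < tol:
            return dict(zip(nodes, new))
        x = new
    return dict(zip(nodes, x))


def exact_walk_distribution(H: nx.DiGraph, length: int) -> dict[tuple, float]:
    """Exact distribution over complete label walks of ``length`` words.

    Mirrors the sampling model independently: start proportional to weighted
    out-degree; steps proportional to edge betweenness within H (computed by
    brute enumeration), falling back to edge weights when all outgoing
    betweenness is zero; walks that halt before reaching ``length`` carry no
    mass. Probabilities are renormalized over complete walks.
    """
    _, edge_btw = brute_betweenness(H, weighted=True)
    out_deg = {n: H.out_degree(n, weight="weight") for n in H.nodes}
    total_out = sum(out_deg.values())

    def step_probs(u):
        succs = list(H.successors(u))
        if not succs:
            return {}
        scores = {v: edge_btw.get((u, v), 0.0) for v in succs}
        if sum(scores.values()) <= 0:
            scores = {v: H[u][v].get("weight", 1.0) for v in succs}
        z = sum(scores.values())
        return {v: s / z for v, s in scores.items()} if z > 0 else {}

    dist: dict[tuple, float] = {}

    def extend(walk, prob):
        if len(walk) == length:
            dist[tuple(walk)] = dist.get(tuple(walk), 0.0) + prob
            return
        for v, p in step_probs(walk[-1]).items():
            extend(walk + [v], prob * p)

    for n in H.nodes:
        if out_deg[n] > 0:
            extend([n], out_deg[n] / total_out)
    z = sum(dist.values())
    return {w: p / z for w, p in dist.items()}


def brute_modularity(G: nx.Graph, blocks) -> float:
    """Weighted Newman modularity, sum_c (e_c - a_c^2), no self-loops."""
    m2 = 2 * sum(d["weight"] for _, _, d in G.edges(data=True))
    q = 0.0
    for block in blocks:
        block = set(block)
        within = sum(
            2 * d["weight"]
            for u, v, d in G.edges(data=True)
            if u in block and v in block
        )
        deg = sum(G.degree(n, weight="weight") for n in block)
        q += within / m2 - (deg / m2) ** 2
    return q
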
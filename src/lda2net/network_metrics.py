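"""Node/edge centralities, Barrat clustering, modularity, percentile filtering.

Shortest-path metrics (betweenness) treat edge weights as tie strengths, so
path cost defaults to 1/weight — a heavier bigram edge is a shorter distance.
Metrics defined for undirected graphs (Barrat clustering coefficient,
modularity) symmetrize the network by summing reciprocal edge weights.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .enrichment_core import TopicNetwork

__all__ = [
    "node_centralities",
    "edge_betweenness",
    "barrat_cc",
    "modularity",
    "filter_network",
    "symmetrize",
]

_DIST = "_distance"


def _as_digraph(network: TopicNetwork | nx.DiGraph) -> nx.DiGraph:
    if isinstance(network, TopicNetwork):
        return network.to_networkx()
    return network


def _with_distances(G: nx.DiGraph, weighted: bool) -> str | None:
    """Attach 1/weight distances for shortest-path metrics; None = unit cost."""
    if not weighted:
        return None
    for _, _, d in G.edges(data=True):
        d[_DIST] = 1.0 / d["weight"] if d.get("weight", 0) > 0 else np.inf
    return _DIST


def symmetrize(network: TopicNetwork | nx.DiGraph) -> nx.Graph:
    """Undirected view with reciprocal edge weights summed; self-loops kept."""
    G = _as_digraph(network)
    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    for u, v, d in G.edges(data=True):
        w = d.get("weight", 1.0)
        if H.has_edge(u, v):
            H[u][v]["weight"] += w
        else:
            H.add_edge(u, v, weight=w)
    return H


def node_centralities(
    network: TopicNetwork | nx.DiGraph, *, weighted_paths: bool = True
) -> pd.DataFrame:
    """Per-word centrality table for one topic network.

    Columns: degree, in_degree, out_degree (edge counts), weighted variants
    (strengths = sums of incident edge weights), pagerank (weighted, sums to
    1) and betweenness (directed shortest paths, unnormalized; path cost
    1/weight unless ``weighted_paths=False``).
    """
    G = _as_digraph(network)
    if G.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    dist = _with_distances(G, weighted_paths)
    pagerank = nx.pagerank(G, weight="weight", tol=1e-12, max_iter=1000)
    betweenness = nx.betweenness_centrality(G, weight=dist, normalized=False)
    rows = []
    for n in G.nodes:
        rows.append(
            {
                "word": n,
                "degree": G.in_degree(n) + G.out_degree(n),
                "in_degree": G.in_degree(n),
                "out_degree": G.out_degree(n),
                "weighted_degree": G.in_degree(n, weight="weight")
                + G.out_degree(n, weight="weight"),
                "weighted_in_degree": G.in_degree(n, weight="weight"),
                "weighted_out_degree": G.out_degree(n, weight="weight"),
                "pagerank": pagerank[n],
                "betweenness": betweenness[n],
            }
        )
    return pd.DataFrame(rows).set_index("word")


def edge_betweenness(
    network: TopicNetwork | nx.DiGraph, *, weighted_paths: bool = True
) -> dict[tuple[str, str], float]:
    """Directed edge betweenness: shortest-path flow through each edge.

    Unnormalized counts of all-pairs shortest paths (fractions under ties);
    path cost 1/weight by default.
    """
    G = _as_digraph(network)
    dist = _with_distances(G, weighted_paths)
    return nx.edge_betweenness_centrality(G, weight=dist, normalized=False)


def barrat_cc(
    network: TopicNetwork | nx.DiGraph,
) -> tuple[pd.Series, float]:
    """Barrat weighted clustering coefficient per node, and its global mean.

    On the symmetrized graph, for node i with strength s_i and degree k_i:

        c_i = 1 / (s_i (k_i - 1)) * sum_{j,h} (w_ij + w_ih) / 2
              over *ordered* neighbor pairs (j, h) that are themselves
              connected (each triangle through i counts twice).

    Nodes with fewer than two neighbors get 0. The global coefficient is the
    mean over nodes with k_i >= 2 (0 if there are none). With uniform weights
    this reduces to the unweighted local clustering coefficient.
    """
    H = symmetrize(network)
    H.remove_edges_from(nx.selfloop_edges(H))
    coeffs = {}
    eligible = []
    for i in H.nodes:
        nbrs = list(H[i])
        k = len(nbrs)
        if k < 2:
            coeffs[i] = 0.0
            continue
        s = sum(H[i][j]["weight"] for j in nbrs)
        acc = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = nbrs[a], nbrs[b]
                if H.has_edge(j, h):
                    # ordered pairs (j,h) and (h,j) together contribute w_ij + w_ih
                    acc += H[i][j]["weight"] + H[i][h]["weight"]
        coeffs[i] = acc / (s * (k - 1)) if s > 0 else 0.0
        eligible.append(coeffs[i])
    global_cc = float(np.mean(eligible)) if eligible else 0.0
    return pd.Series(coeffs, name="barrat_cc"), global_cc


def modularity(
    network: TopicNetwork | nx.DiGraph, partition: Sequence[Iterable[str]]
) -> float:
    """Weighted Newman modularity of a node partition (symmetrized graph).

    The partition must cover every node of the (non-isolated) graph exactly
    once.
    """
    H = symmetrize(network)
    blocks = [set(b) for b in partition]
    seen: set[str] = set()
    for b in blocks:
        if b & seen:
            raise ValueError("partition blocks are not disjoint")
        seen |= b
    if seen != set(H.nodes):
        raise ValueError("partition does not cover the node set exactly")
    return nx.community.modularity(H, blocks, weight="weight")


def filter_network(
    network: TopicNetwork,
    node_pct: float,
    edge_pct: float,
    M: np.ndarray,
    k: int | None = None,
) -> TopicNetwork:
    """Keep only top-percentile words (by topic probability) and edges (by
    weight), then drop dangling edges and isolated words.

    ``node_pct`` / ``edge_pct`` are "top X percent": nodes with M[k, .] at or
    above the (100 - node_pct)th percentile are retained, and likewise edges
    by weight. Ties at the cut value are all kept. 100/100 is the identity.
    """
    if not (0 < node_pct <= 100 and 0 < edge_pct <= 100):
        raise ValueError("percentiles must be in (0, 100]")
    if k is None:
        k = network.topic_id
    M = np.asarray(M, dtype=float)
    probs = M[k]
    node_cut = np.percentile(probs, 100 - node_pct)
    keep_nodes = np.flatnonzero(probs >= node_cut) if node_pct < 100 else np.arange(len(probs))
    coo = network.adjacency.tocoo()
    if coo.nnz == 0:
        return network.copy()
    edge_cut = np.percentile(coo.data, 100 - edge_pct)
    mask = coo.data >= edge_cut if edge_pct < 100 else np.ones(coo.nnz, dtype=bool)
    node_set = set(keep_nodes.tolist())
    mask &= np.fromiter(
        (i in node_set and j in node_set for i, j in zip(coo.row, coo.col)),
        dtype=bool,
        count=coo.nnz,
    )
    A = sparse.csr_matrix(
        (coo.data[mask], (coo.row[mask], coo.col[mask])), shape=network.adjacency.shape
    )
    if A.nnz == 0:
        import warnings

        warnings.warn(
            f"topic {network.topic_id}: filtering emptied the network", stacklevel=2
        )
    return TopicNetwork(
        topic_id=network.topic_id,
        adjacency=A,
        vocab=network.vocab,
        normalized=False,
    )
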
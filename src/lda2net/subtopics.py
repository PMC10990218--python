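"""Subtopic detection: weighted walktrap communities on topic networks.

A subtopic is a community of the topic's word network — a word subset more
densely connected internally than to the rest of the network. Detection uses
the walktrap algorithm (short random walks define node distances, bottom-up
hierarchical merging) on the symmetrized weighted graph, cutting the
dendrogram at maximum modularity. Topics with high partition modularity are
the best candidates for containing real subtopics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import networkx as nx

from .enrichment_core import TopicNetwork
from .network_metrics import modularity as _modularity, symmetrize

__all__ = [
    "CommunityPartition",
    "detect_communities",
    "rank_topics_by_modularity",
    "subgraph",
]


@dataclass
class CommunityPartition:
    """Disjoint word communities of one topic network.

    ``blocks`` are ordered by size (largest first; ties by discovery order),
    jointly covering the network's non-isolated nodes; every node belongs to
    exactly one block. Isolated words are reported separately.
    """

    topic_id: int
    blocks: list[list[str]]
    modularity: float
    isolated: list[str] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return [len(b) for b in self.blocks]

    def membership(self) -> dict[str, int]:
        return {w: c for c, block in enumerate(self.blocks) for w in block}


def detect_communities(
    network: TopicNetwork | nx.DiGraph, steps: int = 4
) -> CommunityPartition:
    """Weighted walktrap partition of a topic network.

    Runs on the symmetrized weighted graph (walktrap is defined for
    undirected graphs); self-loops are ignored and isolated nodes excluded
    from the walk. The dendrogram is cut at the level of maximum modularity.
    Deterministic given the network.
    """
    if steps < 2:
        raise ValueError("walk length must be at least 2")
    topic_id = network.topic_id if isinstance(network, TopicNetwork) else -1
    H = symmetrize(network)
    H.remove_edges_from(nx.selfloop_edges(H))
    isolated = sorted(n for n in H.nodes if H.degree(n) == 0)
    H.remove_nodes_from(isolated)
    if H.number_of_nodes() == 0:
        raise ValueError(f"topic {topic_id}: network has no connected words")
    nodes = list(H.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    edges = [(idx[u], idx[v]) for u, v in H.edges]
    weights = [H[u][v]["weight"] for u, v in H.edges]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    dendrogram = g.community_walktrap(weights=weights, steps=steps)
    clustering = dendrogram.as_clustering()  # cut at max modularity
    blocks = [[nodes[i] for i in block] for block in clustering]
    blocks.sort(key=lambda b: -len(b))
    q = _modularity(H, blocks)
    return CommunityPartition(
        topic_id=topic_id, blocks=blocks, modularity=q, isolated=isolated
    )


def rank_topics_by_modularity(
    partitions: list[CommunityPartition],
) -> list[CommunityPartition]:
    """Order partitions by descending modularity; ties broken by topic id."""
    return sorted(partitions, key=lambda p: (-p.modularity, p.topic_id))


def subgraph(network: TopicNetwork | nx.DiGraph, block: set[str] | list[str]) -> nx.DiGraph:
    """Induced directed weighted subgraph on a community's words.

    Weights are not rescaled. A single-word block yields that word with its
    self-loop, if any.
    """
    block = set(block)
    if not block:
        raise ValueError("empty community block")
    G = network.to_networkx() if isinstance(network, TopicNetwork) else network
    missing = block - set(G.nodes)
    if missing:
        raise ValueError(f"block contains words outside the network: {sorted(missing)[:5]}")
    return G.subgraph(block).copy()
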
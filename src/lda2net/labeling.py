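"""Random-walk n-gram label generation for topics and subtopics.

A label of length l is a realizable directed path of l words through a
community subgraph. The start node is drawn with probability proportional to
weighted out-degree (hub words tend to start phrases); each step follows an
outgoing edge with probability proportional to its edge betweenness on the
community subgraph — a global criterion for how much phrase traffic the
bigram carries. When every outgoing edge of the current word has zero
betweenness, edge weights are used instead. A walk halts early at a word
with no outgoing edge; by default halted walks are discarded. Candidates are
ranked by how often they were sampled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np

from .enrichment_core import TopicNetwork
from .network_metrics import edge_betweenness
from .subtopics import CommunityPartition, subgraph

__all__ = [
    "WalkPolicy",
    "LabelCandidate",
    "start_distribution",
    "transition_distribution",
    "sample_labels",
    "topic_label",
]


@dataclass(frozen=True)
class WalkPolicy:
    """Sampling configuration for label walks."""

    n_walks: int = 1000
    length: int = 2
    seed: int = 0
    short_walk_rule: Literal["discard", "keep"] = "discard"

    def __post_init__(self):
        if self.n_walks < 1:
            raise ValueError("n_walks must be >= 1")
        if self.length < 2:
            raise ValueError("label length must be >= 2")


@dataclass(frozen=True)
class LabelCandidate:
    """A sampled n-gram label with its sampling frequency."""

    words: tuple[str, ...]
    count: int
    share: float

    def __str__(self) -> str:
        return "→".join(self.words)


def start_distribution(H: nx.DiGraph) -> dict[str, float]:
    """Start probabilities: proportional to weighted out-degree."""
    out = {n: H.out_degree(n, weight="weight") for n in H.nodes}
    total = sum(out.values())
    if total <= 0:
        raise ValueError("no node has positive weighted out-degree; no walk possible")
    return {n: d / total for n, d in out.items()}


def transition_distribution(
    H: nx.DiGraph,
    node: str,
    edge_btw: dict[tuple[str, str], float] | None = None,
) -> tuple[list[str], list[float]] | None:
    """Step probabilities out of ``node``; None signals a halt (no out-edges).

    Probability of moving to j is proportional to the edge betweenness of
    (node, j) within H; if all outgoing betweenness values are zero, edge
    weights are used instead.
    """
    if node not in H:
        raise ValueError(f"node {node!r} not in subgraph")
    succs = list(H.successors(node))
    if not succs:
        return None
    if edge_btw is None:
        edge_btw = edge_betweenness(H)
    scores = [edge_btw.get((node, j), 0.0) for j in succs]
    total = sum(scores)
    if total <= 0:
        scores = [H[node][j].get("weight", 1.0) for j in succs]
        total = sum(scores)
        if total <= 0:
            return None
    return succs, [s / total for s in scores]


def sample_labels(
    H: nx.DiGraph | TopicNetwork, policy: WalkPolicy
) -> list[LabelCandidate]:
    """Sample label candidates by seeded random walks over a subgraph.

    Returns candidates ranked by descending count, ties by lexicographic word
    order; shares sum to 1 over the returned table. Raises if no walk of the
    requested length completes.
    """
    if isinstance(H, TopicNetwork):
        H = H.to_networkx()
    rng = np.random.default_rng(policy.seed)
    starts = start_distribution(H)
    start_nodes = list(starts)
    start_cum = np.cumsum([starts[n] for n in start_nodes])
    btw = edge_betweenness(H)
    # precompute per-node successor tables once
    trans: dict[str, tuple[list[str], np.ndarray] | None] = {}
    for n in H.nodes:
        t = transition_distribution(H, n, btw)
        trans[n] = None if t is None else (t[0], np.cumsum(t[1]))
    counts: Counter[tuple[str, ...]] = Counter()
    completed = 0
    for _ in range(policy.n_walks):
        node = start_nodes[
            int(np.searchsorted(start_cum, rng.random() * start_cum[-1], side="right"))
        ]
        walk = [node]
        while len(walk) < policy.length:
            t = trans[walk[-1]]
            if t is None:
                break
            succs, cum = t
            walk.append(succs[int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))])
        if len(walk) == policy.length:
            counts[tuple(walk)] += 1
            completed += 1
        elif policy.short_walk_rule == "keep":
            counts[tuple(walk)] += 1
            completed += 1
    if completed == 0:
        raise ValueError(
            f"no walk of length {policy.length} completed out of {policy.n_walks}"
        )
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [LabelCandidate(words=w, count=c, share=c / completed) for w, c in ranked]


def topic_label(
    network: TopicNetwork | nx.DiGraph,
    partition: CommunityPartition,
    policy: WalkPolicy,
) -> LabelCandidate:
    """Topic-level label: top candidate of the largest community.

    Sampling labels on the whole topic network tends to spread mass over many
    rare candidates; the largest subtopic gives a sharper label. Size ties go
    to the lower community index.
    """
    if not partition.blocks:
        raise ValueError("partition has no communities")
    largest = max(partition.blocks, key=len)  # max() keeps the first on ties
    H = subgraph(network, largest)
    return sample_labels(H, policy)[0]
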
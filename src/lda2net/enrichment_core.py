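"""Per-topic weighted directed word networks from bigram counts + topic model.

The enrichment combines two sources of evidence for each observed bigram
b = (w_i, w_j) and each topic k:

* the *counts-weight* ``C[b, k] = sum_d S[b, d] * Q[d, k]`` — how often the
  bigram occurs, credited to topics in proportion to document mixtures;
* the *probs-weight* ``M[k, i] * M[k, j]`` — the topic-specific probabilities
  of the two member words.

Their product is the directed edge weight of topic k's word network. Entries
at word pairs never observed adjacently are structural zeros: the network is
supported only on the observed bigram vocabulary. Each topic's adjacency is
finally normalized so that the grand sum of its entries is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from scipy import sparse

from .corpus_prep import BigramVocabulary, Vocabulary

__all__ = [
    "TopicNetwork",
    "counts_weights",
    "probs_weight",
    "edge_weights",
    "normalize",
    "build_all_networks",
    "DegenerateTopicError",
]


class DegenerateTopicError(ValueError):
    """Raised when a topic's network has no positive edge weight."""


@dataclass
class TopicNetwork:
    """Weighted directed adjacency over the word vocabulary for one topic.

    The node set is the full vocabulary for every topic; only the weights
    differ. ``adjacency`` is NW x NW sparse, nonzero only at observed bigrams.
    """

    topic_id: int
    adjacency: sparse.csr_matrix
    vocab: Vocabulary
    normalized: bool = False

    @property
    def total_weight(self) -> float:
        return float(self.adjacency.sum())

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz

    def edges(self):
        """Yield (source_word, target_word, weight) for every nonzero entry."""
        coo = self.adjacency.tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            yield self.vocab[i], self.vocab[j], float(w)

    def to_networkx(self, include_isolated: bool = False) -> nx.DiGraph:
        """Directed weighted graph of the nonzero entries.

        By default only words incident to at least one edge become nodes;
        with ``include_isolated=True`` the full vocabulary is used.
        """
        G = nx.DiGraph(topic_id=self.topic_id)
        if include_isolated:
            G.add_nodes_from(self.vocab.words)
        G.add_weighted_edges_from(self.edges())
        return G

    def copy(self) -> "TopicNetwork":
        return replace(self, adjacency=self.adjacency.copy())


def counts_weights(S: sparse.spmatrix, Q: np.ndarray) -> sparse.csr_matrix:
    """Counts-weights C = S @ Q, a bigrams x topics table.

    ``C[b, k]`` sums, over documents, the bigram's count times the document's
    topic-k proportion.
    """
    S = sparse.csr_matrix(S)
    Q = np.asarray(Q, dtype=float)
    if S.shape[1] != Q.shape[0]:
        raise ValueError(
            f"S has {S.shape[1]} document columns but Q has {Q.shape[0]} rows"
        )
    return sparse.csr_matrix(S @ Q)


def probs_weight(M: np.ndarray, k: int, i: int, j: int) -> float:
    """Probs-weight of bigram (w_i, w_j) under topic k: M[k, i] * M[k, j]."""
    return float(M[k, i] * M[k, j])


def edge_weights(
    C: sparse.spmatrix,
    M: np.ndarray,
    k: int,
    bigrams: BigramVocabulary,
    vocab: Vocabulary,
) -> TopicNetwork:
    """Unnormalized topic-k network: weight C[b, k] * M[k, i] * M[k, j].

    Direction is preserved: (w_i, w_j) and (w_j, w_i) are independent
    entries, and word pairs outside the observed bigram vocabulary stay
    structurally zero. Self-loop bigrams (repeated words) are kept.
    """
    C = sparse.csc_matrix(C)
    M = np.asarray(M, dtype=float)
    nb, nw = len(bigrams), len(vocab)
    if C.shape[0] != nb:
        raise ValueError(f"C has {C.shape[0]} rows but bigram vocabulary has {nb}")
    if M.shape[1] != nw:
        raise ValueError(f"M has {M.shape[1]} columns but vocabulary has {nw}")
    ck = np.asarray(C[:, k].todense()).ravel()
    rows = np.fromiter((vocab.index[b[0]] for b in bigrams), dtype=np.int64, count=nb)
    cols = np.fromiter((vocab.index[b[1]] for b in bigrams), dtype=np.int64, count=nb)
    vals = ck * M[k, rows] * M[k, cols]
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(nw, nw))
    A.eliminate_zeros()
    return TopicNetwork(topic_id=k, adjacency=A, vocab=vocab, normalized=False)


def normalize(network: TopicNetwork) -> TopicNetwork:
    """Divide all entries by their grand total so they sum to 1.

    The zero pattern is unchanged; idempotent. Raises
    :class:`DegenerateTopicError` if the network has no positive weight.
    """
    total = network.total_weight
    if total <= 0:
        raise DegenerateTopicError(
            f"topic {network.topic_id}: all edge weights are zero"
        )
    A = network.adjacency / total
    return TopicNetwork(
        topic_id=network.topic_id,
        adjacency=sparse.csr_matrix(A),
        vocab=network.vocab,
        normalized=True,
    )


def build_all_networks(
    S: sparse.spmatrix,
    Q: np.ndarray,
    M: np.ndarray,
    bigrams: BigramVocabulary,
    vocab: Vocabulary,
    *,
    keep_unnormalized: bool = False,
) -> list[TopicNetwork]:
    """One normalized network per topic, sharing the vocabulary node set.

    A degenerate topic (no positive edge weight) produces an empty network
    and a warning rather than an error.
    """
    C = counts_weights(S, Q)
    K = np.asarray(M).shape[0]
    networks: list[TopicNetwork] = []
    for k in range(K):
        net = edge_weights(C, M, k, bigrams, vocab)
        if keep_unnormalized:
            networks.append(net)
            continue
        try:
            networks.append(normalize(net))
        except DegenerateTopicError as exc:
            warnings.warn(f"{exc}; emitting empty network", stacklevel=2)
            networks.append(net)
    return networks
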
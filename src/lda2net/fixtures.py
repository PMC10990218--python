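"""Synthetic corpora with planted topic structure and bigram chains.

The generator emulates exactly the structure the enrichment is designed to
expose: documents are topic mixtures (bag-of-words, recoverable by any LDA-
style estimator), but *within* each topic words follow a first-order Markov
chain over that topic's signature words — syntagmatic structure invisible to
bag-of-words models yet recorded in the observed bigrams. Per token, a topic
is drawn from the document's Dirichlet mixture, then the next word of that
topic's chain is emitted (each topic keeps its own chain position within a
document); with probability ``noise_rate`` an off-chain noise word is emitted
instead. Sentence breaks are inserted at random so cleaned documents contain
multiple token runs.

This is a stylized testbed: it does not emulate the scale, vocabulary or
section structure of real abstract corpora.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_prep import Document

__all__ = ["PlantedTopicSpec", "default_specs", "generate_corpus"]


@dataclass(frozen=True)
class PlantedTopicSpec:
    """One planted topic: signature words joined by a weighted bigram chain."""

    signature_words: tuple[str, ...]
    chain_edges: tuple[tuple[str, str, float], ...]
    doc_topic_concentration: float = 0.1
    noise_rate: float = 0.1

    def __post_init__(self):
        if not self.chain_edges:
            raise ValueError("planted topic has an empty chain")
        sig = set(self.signature_words)
        for u, v, w in self.chain_edges:
            if u not in sig or v not in sig:
                raise ValueError(f"chain edge ({u}, {v}) leaves the signature words")
            if w <= 0:
                raise ValueError("chain transition weights must be positive")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")

    def edge_set(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v, _ in self.chain_edges}


def default_specs(
    n_topics: int = 3,
    words_per_topic: int = 15,
    doc_topic_concentration: float = 0.1,
    noise_rate: float = 0.1,
) -> list[PlantedTopicSpec]:
    """Disjoint cyclic chains of lowercase signature words, one per topic.

    Topic t's words are ``t{t}{aa..}``; its chain visits them in a cycle with
    unit transition weights, giving ``words_per_topic`` distinct planted
    directed edges per topic.
    """
    if n_topics < 2:
        raise ValueError("need at least 2 planted topics")
    specs = []
    for t in range(n_topics):
        words = tuple(
            f"t{t}{chr(97 + i // 26)}{chr(97 + i % 26)}x" for i in range(words_per_topic)
        )
        edges = tuple(
            (words[i], words[(i + 1) % len(words)], 1.0) for i in range(len(words))
        )
        specs.append(
            PlantedTopicSpec(
                signature_words=words,
                chain_edges=edges,
                doc_topic_concentration=doc_topic_concentration,
                noise_rate=noise_rate,
            )
        )
    return specs


def generate_corpus(
    specs: list[PlantedTopicSpec],
    n_docs: int = 500,
    doc_length: int = 80,
    seed: int = 0,
    n_noise_words: int = 8,
    sentence_break_prob: float = 0.08,
) -> tuple[list[Document], dict]:
    """Generate a corpus of planted-topic documents plus ground truth.

    Returns the documents and a ground-truth dict with the true per-document
    topic mixtures, each topic's signature words and chain edges, and the
    shared noise vocabulary. Seeded and fully reproducible.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 topic specs")
    if doc_length < 10:
        raise ValueError("doc_length must be at least 10")
    rng = np.random.default_rng(seed)
    K = len(specs)
    noise_words = [f"noise{chr(97 + i)}word" for i in range(n_noise_words)]
    # per-topic transition tables: word -> (successors, cumulative weights)
    chains = []
    for spec in specs:
        table: dict[str, tuple[list[str], np.ndarray]] = {}
        for u, v, w in spec.chain_edges:
            table.setdefault(u, ([], []))[0].append(v)
            table[u][1].append(w)
        chains.append(
            {u: (succ, np.cumsum(ws) / np.sum(ws)) for u, (succ, ws) in table.items()}
        )
    start_words = [list(c) for c in chains]
    conc = np.array([s.doc_topic_concentration for s in specs])
    mixtures = rng.dirichlet(conc, size=n_docs)
    docs: list[Document] = []
    for d in range(n_docs):
        theta = mixtures[d]
        state: list[str | None] = [None] * K
        tokens: list[str] = []
        zs = rng.choice(K, size=doc_length, p=theta)
        us = rng.random(doc_length)
        for z, u in zip(zs, us):
            spec = specs[z]
            if u < spec.noise_rate:
                tokens.append(noise_words[rng.integers(len(noise_words))])
            else:
                cur = state[z]
                if cur is None or cur not in chains[z]:
                    nxt = start_words[z][rng.integers(len(start_words[z]))]
                else:
                    succ, cum = chains[z][cur]
                    nxt = succ[int(np.searchsorted(cum, rng.random(), side="right"))]
                tokens.append(nxt)
                state[z] = nxt
            if rng.random() < sentence_break_prob:
                tokens.append(".")
        text = " ".join(tokens).replace(" .", ".")
        docs.append(Document(id=f"doc{d:05d}", text=text))
    truth = {
        "mixtures": mixtures,
        "topics": [
            {
                "signature_words": list(s.signature_words),
                "chain_edges": [list(e) for e in s.chain_edges],
            }
            for s in specs
        ],
        "noise_words": noise_words,
        "seed": seed,
    }
    return docs, truth
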
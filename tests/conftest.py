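import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose _oracles to tests

from lda2net import (
    build_all_networks,
    default_specs,
    estimate_topics,
    generate_corpus,
    prepare_corpus,
)


@pytest.fixture(scope="session")
def planted():
    """A small planted-topic corpus run end-to-end once per session.

    Three disjoint 15-word cyclic chains, 300 documents of ~80 tokens,
    noise rate 0.1, topic model estimated with matched K.
    """
    specs = default_specs(n_topics=3, words_per_topic=15, noise_rate=0.1)
    docs, truth = generate_corpus(specs, n_docs=300, doc_length=80, seed=7)
    prep = prepare_corpus(docs)
    M, Q = estimate_topics(prep.U, 3, seed=1)
    networks = build_all_networks(prep.S, Q, M, prep.bigrams, prep.vocab)
    return {
        "specs": specs,
        "docs": docs,
        "truth": truth,
        "prep": prep,
        "M": M,
        "Q": Q,
        "networks": networks,
    }


@pytest.fixture
def two_triangles():
    """Two equal-weight (bidirectional) triangles joined by one weak bridge."""
    G = nx.DiGraph()
    for a, b in [("a", "b"), ("b", "c"), ("c", "a"), ("x", "y"), ("y", "z"), ("z", "x")]:
        G.add_edge(a, b, weight=1.0)
        G.add_edge(b, a, weight=1.0)
    G.add_edge("c", "x", weight=0.05)
    return G


def random_digraph(rng: np.random.Generator, n_nodes: int, p: float = 0.4) -> nx.DiGraph:
    """Random weighted DiGraph with at least one edge (shared test helper)."""
    while True:
        G = nx.DiGraph()
        G.add_nodes_from(range(n_nodes))
        for i in range(n_nodes):
            for j in range(n_nodes):
                if i != j and rng.random() < p:
                    G.add_edge(i, j, weight=float(rng.uniform(0.1, 3.0)))
        if G.number_of_edges() > 0:
            return G
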
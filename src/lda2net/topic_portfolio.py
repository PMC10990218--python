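"""Topic-level summaries, Jensen-Shannon divergence, GMM clustering, matching.

Each topic is profiled by four scalars: the mean and variance of its
proportion across documents, the Jensen-Shannon divergence between its two
edge-weight components (counts-weights as the data distribution, probs-
weights as the model), and the global Barrat clustering coefficient of its
network. Standardized profiles are clustered with Gaussian finite mixtures,
selecting the component count and covariance structure by BIC — separating
specialized topics (high variance, low divergence) from cross-cutting ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .corpus_prep import BigramVocabulary, Vocabulary
from .enrichment_core import DegenerateTopicError, TopicNetwork, counts_weights
from .network_metrics import barrat_cc, node_centralities

__all__ = [
    "TopicSummary",
    "TopicClusterAssignment",
    "topic_mean_variance",
    "jsd",
    "topic_jsd",
    "topic_summaries",
    "cluster_topics",
    "jaccard_topics",
    "centrality_lda_correlations",
]

CLUSTER_FEATURES = ("mean", "variance", "jsd", "bcc")


@dataclass(frozen=True)
class TopicSummary:
    """Scalar profile of one topic."""

    topic_id: int
    mean: float
    variance: float
    jsd: float
    bcc: float
    modularity: float | None = None


@dataclass(frozen=True)
class TopicClusterAssignment:
    topic_id: int
    cluster: int
    n_clusters: int
    model_name: str


def topic_mean_variance(Q: np.ndarray, k: int) -> tuple[float, float]:
    """Population mean and variance of topic k's proportion over documents."""
    col = np.asarray(Q, dtype=float)[:, k]
    mu = col.mean()
    return float(mu), float(np.mean((col - mu) ** 2))


def jsd(P: np.ndarray, R: np.ndarray, base: float = 2.0) -> float:
    """Jensen-Shannon divergence between two discrete distributions.

    D_JS(P, R) = 1/2 KL(P || M) + 1/2 KL(R || M) with M = (P + R)/2 and
    0*log(0) := 0. With base-2 logarithms the value lies in [0, 1]: 0 for
    identical distributions, 1 for disjoint supports. Symmetric.
    """
    P = np.asarray(P, dtype=float).ravel()
    R = np.asarray(R, dtype=float).ravel()
    if P.shape != R.shape:
        raise ValueError("distributions must share a common support")
    if (P < 0).any() or (R < 0).any():
        raise ValueError("distributions must be non-negative")
    if abs(P.sum() - 1.0) > 1e-8 or abs(R.sum() - 1.0) > 1e-8:
        raise ValueError("distributions must each sum to 1 (within 1e-8)")
    M = 0.5 * (P + R)
    log_base = np.log(base)

    def _kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / M[mask])) / log_base)

    return 0.5 * _kl(P) + 0.5 * _kl(R)


def topic_jsd(counts_col: np.ndarray, probs_col: np.ndarray) -> float:
    """JSD between a topic's counts-weight and probs-weight distributions.

    Both vectors live on the observed bigram vocabulary and are renormalized
    to sum 1 there; counts-weights play the data role, probs-weights the
    model role. A zero-sum component means a degenerate topic.
    """
    c = np.asarray(counts_col, dtype=float).ravel()
    p = np.asarray(probs_col, dtype=float).ravel()
    if c.sum() <= 0 or p.sum() <= 0:
        raise DegenerateTopicError("zero-sum weight component for topic")
    return jsd(c / c.sum(), p / p.sum())


def _probs_weights_on_bigrams(
    M: np.ndarray, k: int, bigrams: BigramVocabulary, vocab: Vocabulary
) -> np.ndarray:
    rows = np.fromiter((vocab.index[b[0]] for b in bigrams), dtype=np.int64, count=len(bigrams))
    cols = np.fromiter((vocab.index[b[1]] for b in bigrams), dtype=np.int64, count=len(bigrams))
    return M[k, rows] * M[k, cols]


def topic_summaries(
    S: sparse.spmatrix,
    Q: np.ndarray,
    M: np.ndarray,
    networks: list[TopicNetwork],
    bigrams: BigramVocabulary,
    vocab: Vocabulary,
    modularities: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Summary table: topic, mean, variance, jsd, bcc (+ modularity if given)."""
    M = np.asarray(M, dtype=float)
    Q = np.asarray(Q, dtype=float)
    C = counts_weights(S, Q)
    rows = []
    for net in networks:
        k = net.topic_id
        mu, var = topic_mean_variance(Q, k)
        ck = np.asarray(C[:, k].todense()).ravel()
        pk = _probs_weights_on_bigrams(M, k, bigrams, vocab)
        _, bcc = barrat_cc(net)
        rows.append(
            {
                "topic": k,
                "mean": mu,
                "variance": var,
                "jsd": topic_jsd(ck, pk),
                "bcc": bcc,
                "modularity": (modularities or {}).get(k, np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("topic")


def cluster_topics(
    summaries: pd.DataFrame,
    seed: int = 0,
    features: tuple[str, ...] = CLUSTER_FEATURES,
    max_components: int | None = None,
    covariance_types: tuple[str, ...] = ("full", "tied", "diag", "spherical"),
    reg_covar: float = 1e-3,
) -> list[TopicClusterAssignment]:
    """Cluster standardized topic profiles with Gaussian finite mixtures.

    Fits every (covariance structure, component count) pair on z-scored
    features and keeps the fit with the lowest BIC; returns hard assignments.
    ``reg_covar`` floors component variances: since features are z-scored to
    unit variance, the default 1e-3 prevents components from collapsing onto
    single points and gaming the BIC comparison.
    """
    from sklearn.mixture import GaussianMixture

    X = summaries.loc[:, list(features)].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 topics to cluster")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    if max_components is None:
        max_components = min(9, n - 1)
    best = None
    for cov in covariance_types:
        for n_comp in range(1, max_components + 1):
            gmm = GaussianMixture(
                n_components=n_comp,
                covariance_type=cov,
                random_state=seed,
                reg_covar=reg_covar,
                n_init=3,
            )
            gmm.fit(Z)
            bic = gmm.bic(Z)
            if best is None or bic < best[0]:
                best = (bic, gmm, cov)
    _, gmm, cov = best
    labels = gmm.predict(Z)
    return [
        TopicClusterAssignment(
            topic_id=int(t),
            cluster=int(c),
            n_clusters=gmm.n_components,
            model_name=cov,
        )
        for t, c in zip(summaries.index, labels)
    ]


def jaccard_topics(
    row_a: np.ndarray,
    row_b: np.ndarray,
    top_n: int = 25,
    vocab_a: Vocabulary | None = None,
    vocab_b: Vocabulary | None = None,
) -> float:
    """Jaccard similarity of two topics' top-n word sets.

    Used to match topics across models estimated on the same corpus. Word
    identity uses vocabulary strings when vocabularies are given, column
    indices otherwise.
    """
    row_a = np.asarray(row_a, dtype=float).ravel()
    row_b = np.asarray(row_b, dtype=float).ravel()
    if top_n > len(row_a) or top_n > len(row_b):
        raise ValueError("top_n exceeds vocabulary size")
    top_a = np.argsort(-row_a, kind="stable")[:top_n]
    top_b = np.argsort(-row_b, kind="stable")[:top_n]
    set_a = {vocab_a[i] for i in top_a} if vocab_a else set(top_a.tolist())
    set_b = {vocab_b[i] for i in top_b} if vocab_b else set(top_b.tolist())
    return len(set_a & set_b) / len(set_a | set_b)


_CORR_METRICS = ["prob", "degree", "in_degree", "out_degree", "betweenness", "pagerank"]


def centrality_lda_correlations(
    networks: list[TopicNetwork],
    M: np.ndarray,
    top_n: int = 30,
    tables: dict[int, pd.DataFrame] | None = None,
) -> dict[str, pd.DataFrame]:
    """Pearson and Spearman correlations between centralities and topic-word
    probabilities, pooled over topics.

    Returns four matrices: pearson/spearman over all words of each network
    and over each topic's top-n words by probability. Constant columns give
    missing (NaN) correlations.
    """
    M = np.asarray(M, dtype=float)
    pooled_all, pooled_top = [], []
    for net in networks:
        tab = tables[net.topic_id] if tables else node_centralities(net)
        k = net.topic_id
        probs = pd.Series(
            {w: M[k, net.vocab.index[w]] for w in tab.index}, name="prob"
        )
        df = pd.concat([probs, tab], axis=1)[_CORR_METRICS]
        pooled_all.append(df)
        pooled_top.append(df.nlargest(min(top_n, len(df)), "prob"))
    all_df = pd.concat(pooled_all, ignore_index=True)
    top_df = pd.concat(pooled_top, ignore_index=True)
    return {
        "pearson_all": all_df.corr(method="pearson"),
        "spearman_all": all_df.corr(method="spearman"),
        "pearson_top": top_df.corr(method="pearson"),
        "spearman_top": top_df.corr(method="spearman"),
    }
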
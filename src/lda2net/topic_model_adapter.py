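"""Topic-model matrices M (topic x word) and Q (doc x topic).

The enrichment is deterministic and agnostic to how the topic model was
estimated: this module either validates externally estimated matrices or
delegates estimation on the document-term table to scikit-learn's variational
LDA. Any estimator producing row-stochastic M and Q works — correlated or
sparse-additive topic models plug in through :func:`load_topic_model`
unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .corpus_prep import Vocabulary

__all__ = ["validate_matrices", "load_topic_model", "estimate_topics"]

_ROW_SUM_TOL = 1e-6


def _validate_stochastic(name: str, X: np.ndarray, tol: float = _ROW_SUM_TOL) -> np.ndarray:
    """Check non-negativity and row sums; renormalize rows off by <= tol."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be a 2-D table")
    if (X < 0).any():
        raise ValueError(f"{name} contains negative entries")
    sums = X.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError(f"{name} has an all-zero row")
    if np.abs(sums - 1.0).max() > tol:
        raise ValueError(
            f"{name} rows deviate from unit sum by more than {tol:g} "
            f"(max deviation {np.abs(sums - 1.0).max():.3g})"
        )
    return X / sums[:, None]


def validate_matrices(
    M: np.ndarray, Q: np.ndarray, vocab: Vocabulary | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Validate and exactly renormalize a (M, Q) pair.

    M is K x NW with rows summing to 1 (one word distribution per topic);
    Q is ND x K with rows summing to 1 (one topic mixture per document).
    """
    M = _validate_stochastic("M (topic-word matrix)", M)
    Q = _validate_stochastic("Q (doc-topic matrix)", Q)
    if M.shape[0] != Q.shape[1]:
        raise ValueError(
            f"topic count mismatch: M has {M.shape[0]} topics, Q has {Q.shape[1]}"
        )
    if vocab is not None and M.shape[1] != len(vocab):
        raise ValueError(
            f"M has {M.shape[1]} word columns but vocabulary has {len(vocab)} words"
        )
    return M, Q


def load_topic_model(
    m_path: str | Path,
    q_path: str | Path,
    vocab: Vocabulary | None = None,
    *,
    log: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Load externally estimated M and Q from CSV files.

    The M file must carry word names as column headers; if ``vocab`` is given
    its columns are aligned to the vocabulary order (error on mismatch). With
    ``log=True`` entries are interpreted as log-probabilities and
    exponentiated before validation.
    """
    m_df = pd.read_csv(m_path, index_col=0)
    q_df = pd.read_csv(q_path, index_col=0)
    if vocab is not None:
        missing = [w for w in vocab.words if w not in m_df.columns]
        if missing:
            raise ValueError(
                f"M is missing {len(missing)} vocabulary words (e.g. {missing[:5]})"
            )
        if m_df.shape[1] != len(vocab):
            raise ValueError(
                f"M has {m_df.shape[1]} columns but vocabulary has {len(vocab)} words"
            )
        m_df = m_df[vocab.words]
    M = m_df.to_numpy(dtype=float)
    Q = q_df.to_numpy(dtype=float)
    if log:
        if (M > 0).any() or (Q > 0).any():
            raise ValueError("log=True but matrices contain positive entries")
        M, Q = np.exp(M), np.exp(Q)
    return validate_matrices(M, Q, vocab)


def estimate_topics(
    U: sparse.spmatrix | np.ndarray,
    K: int,
    seed: int = 0,
    iterations: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate (M, Q) from the doc-term table with batch variational LDA.

    Fixed ``seed`` gives bit-reproducible output. The enrichment downstream
    does not depend on the backend; this is a convenience default.
    """
    from sklearn.decomposition import LatentDirichletAllocation

    U = sparse.csr_matrix(U)
    nd, nw = U.shape
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > nw:
        raise ValueError(f"K={K} exceeds vocabulary size {nw}")
    if nd == 0 or U.nnz == 0:
        raise ValueError("U is empty")
    lda = LatentDirichletAllocation(
        n_components=K,
        learning_method="batch",
        max_iter=iterations,
        random_state=seed,
    )
    Q = lda.fit_transform(U)
    M = lda.components_ / lda.components_.sum(axis=1)[:, None]
    Q = Q / Q.sum(axis=1)[:, None]
    return validate_matrices(M, Q)
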
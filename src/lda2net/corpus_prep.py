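"""Corpus cleaning, vocabularies and count tables.

Turns raw documents into the two sparse count tables that drive the
enrichment: a document x word table ``U`` (the bag-of-words input to topic
estimation) and a bigram x document table ``S`` holding the observed
frequencies of ordered adjacent word pairs — the syntagmatic evidence that
bag-of-words models discard.

Cleaning rules
--------------
* Section headers (runs of >= 2 consecutive all-caps words at the start of the
  text or after sentence punctuation) are removed before tokenization.
* Arabic and Roman numerals, stopwords (case-insensitive) and tokens shorter
  than three characters are removed from the string *before* bigram
  tokenization, so two content words separated only by removed material still
  form a bigram.
* All punctuation except apostrophes and quotation marks breaks the token
  stream: a bigram never spans a punctuation break.
* Tokens are lower-cased unless they are acronyms. An acronym is an
  all-uppercase token of length >= 2 after stripping digits ("RNA", "CI",
  "AAs" is not — mixed case); acronyms also bypass the minimum-length rule.
* Words are kept in the vocabulary only if they occur at least ``min_rate``
  times per token (default once per million tokens).
* Documents are kept only if they contain at least ``min_doc_words``
  vocabulary tokens (default ten).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from ._stopwords import SNOWBALL_EN

__all__ = [
    "Document",
    "Vocabulary",
    "BigramVocabulary",
    "PreparedCorpus",
    "clean_text",
    "extract_bigrams",
    "build_vocabulary",
    "filter_documents",
    "build_count_tables",
    "prepare_corpus",
]

TokenRuns = list[list[str]]

#: runs of >=2 all-caps words at string start or after sentence punctuation
DEFAULT_HEADER_PATTERN = r"(^|[.!?;:])\s*(?:[A-Z][A-Z0-9]*[A-Z]\b\s+)+[A-Z][A-Z0-9]*[A-Z]\b"

# every non-word character except whitespace, apostrophes and quotes is a break
_RUN_BREAK_RE = re.compile(r"[^\w\s'\"’‘“”]+")
_QUOTE_CHARS = "'\"’‘“”"
_ARABIC_RE = re.compile(r"\d+(?:[.,]\d+)*")
# Roman numerals over {I, V, X} only (phase/section numbering: II, IV, XII...);
# wider alphabets collide with real acronyms such as CI, MI or DC.
_ROMAN_RE = re.compile(r"(?:XC|XL|L?X{0,3})(?:IX|IV|V?I{0,3})")


@dataclass(frozen=True)
class Document:
    """A raw corpus item: opaque id, raw text, optional calendar date."""

    id: str
    text: str
    date: _date | None = None


class Vocabulary:
    """Ordered list of unique retained word types with an index."""

    def __init__(self, words: Iterable[str]):
        self.words: list[str] = list(words)
        self.index: dict[str, int] = {w: i for i, w in enumerate(self.words)}
        if len(self.index) != len(self.words):
            raise ValueError("vocabulary contains duplicate words")

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def __getitem__(self, i: int) -> str:
        return self.words[i]

    def __iter__(self):
        return iter(self.words)

    def __eq__(self, other) -> bool:
        return isinstance(other, Vocabulary) and self.words == other.words

    def __repr__(self) -> str:
        return f"Vocabulary({len(self)} words)"


class BigramVocabulary:
    """Ordered list of unique *ordered* word pairs observed adjacently.

    (w_i, w_j) and (w_j, w_i) are distinct entries: a bigram is an oriented
    edge between two words.
    """

    def __init__(self, bigrams: Iterable[tuple[str, str]]):
        self.bigrams: list[tuple[str, str]] = [tuple(b) for b in bigrams]
        self.index: dict[tuple[str, str], int] = {b: i for i, b in enumerate(self.bigrams)}
        if len(self.index) != len(self.bigrams):
            raise ValueError("bigram vocabulary contains duplicate pairs")

    def __len__(self) -> int:
        return len(self.bigrams)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.index

    def __getitem__(self, i: int) -> tuple[str, str]:
        return self.bigrams[i]

    def __iter__(self):
        return iter(self.bigrams)

    def __repr__(self) -> str:
        return f"BigramVocabulary({len(self)} bigrams)"


def is_acronym(token: str) -> bool:
    """All-uppercase after stripping digits, length >= 2 (e.g. "RNA", "CI")."""
    if len(token) < 2:
        return False
    letters = re.sub(r"\d", "", token)
    return bool(letters) and letters.isalpha() and letters.isupper()


def _is_number(token: str) -> bool:
    if _ARABIC_RE.fullmatch(token):
        return True
    # Roman numerals only in their canonical uppercase form
    return bool(token) and bool(_ROMAN_RE.fullmatch(token))


def clean_text(
    raw: str,
    stopwords: Iterable[str] | None = None,
    *,
    header_pattern: str | None = DEFAULT_HEADER_PATTERN,
    min_chars: int = 3,
    keep_acronyms: bool = True,
) -> TokenRuns:
    """Clean a raw string into an ordered sequence of token runs.

    Within a run, retained tokens were adjacent in the source text with no
    intervening punctuation (apostrophes and quotes excepted). Returns an
    empty list for empty/fully filtered input.
    """
    if not raw or not raw.strip():
        return []
    stop = {s.lower() for s in (SNOWBALL_EN if stopwords is None else stopwords)}
    text = raw
    if header_pattern:
        text = re.sub(header_pattern, r"\1 ", text)
    runs: TokenRuns = []
    for segment in _RUN_BREAK_RE.split(text):
        run: list[str] = []
        for tok in segment.split():
            tok = tok.strip(_QUOTE_CHARS)
            if not tok or _is_number(tok) or tok.lower() in stop:
                continue
            if keep_acronyms and is_acronym(tok):
                run.append(tok)
            elif len(tok) >= min_chars:
                run.append(tok.lower())
        if run:
            runs.append(run)
    return runs


def extract_bigrams(
    runs: TokenRuns, vocab: Vocabulary | None = None
) -> Counter[tuple[str, str]]:
    """Count ordered adjacent token pairs within runs.

    Pairs never span run boundaries. If ``vocab`` is given, only pairs whose
    both members belong to it are counted (pairs straddling an out-of-vocab
    token are dropped, not bridged).
    """
    counts: Counter[tuple[str, str]] = Counter()
    for run in runs:
        for a, b in zip(run, run[1:]):
            if vocab is None or (a in vocab and b in vocab):
                counts[(a, b)] += 1
    return counts


def build_vocabulary(
    cleaned: Sequence[TokenRuns] | Mapping[str, TokenRuns],
    min_rate: float = 1e-6,
) -> Vocabulary:
    """Build the word vocabulary from cleaned token runs.

    A word is retained iff its corpus-wide token frequency is at least
    ``min_rate`` (default: once per million tokens). Words appear in first-seen
    corpus order.
    """
    runs_iter = cleaned.values() if isinstance(cleaned, Mapping) else cleaned
    counts: Counter[str] = Counter()
    order: list[str] = []
    total = 0
    for runs in runs_iter:
        for run in runs:
            for tok in run:
                if tok not in counts:
                    order.append(tok)
                counts[tok] += 1
                total += 1
    if total == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    threshold = min_rate * total
    return Vocabulary(w for w in order if counts[w] >= threshold)


def filter_documents(
    corpus: Sequence[Document],
    vocab: Vocabulary,
    cleaned: Sequence[TokenRuns] | None = None,
    min_doc_words: int = 10,
    **clean_kwargs,
) -> tuple[list[Document], list[TokenRuns]]:
    """Retain documents containing at least ``min_doc_words`` vocabulary tokens.

    Returns the retained documents together with their token runs. Raises if
    every document is filtered out.
    """
    if cleaned is None:
        cleaned = [clean_text(d.text, **clean_kwargs) for d in corpus]
    if len(cleaned) != len(corpus):
        raise ValueError("cleaned runs do not align with corpus")
    kept_docs: list[Document] = []
    kept_runs: list[TokenRuns] = []
    for doc, runs in zip(corpus, cleaned):
        n_vocab_tokens = sum(1 for run in runs for tok in run if tok in vocab)
        if n_vocab_tokens >= min_doc_words:
            kept_docs.append(doc)
            kept_runs.append(runs)
    if not kept_docs:
        raise ValueError(
            f"all {len(corpus)} documents were filtered out "
            f"(none contains >= {min_doc_words} vocabulary tokens)"
        )
    return kept_docs, kept_runs


def build_count_tables(
    cleaned: Sequence[TokenRuns], vocab: Vocabulary
) -> tuple[sparse.csr_matrix, sparse.csr_matrix, BigramVocabulary]:
    """Build U (docs x words), S (bigrams x docs) and the bigram vocabulary.

    The bigram vocabulary contains exactly the ordered pairs observed
    adjacently (within a run, both members in ``vocab``) at least once in the
    corpus, in lexicographic order — so it is invariant under document
    reordering.
    """
    nd, nw = len(cleaned), len(vocab)
    u_rows: list[int] = []
    u_cols: list[int] = []
    u_vals: list[int] = []
    per_doc_bigrams: list[Counter[tuple[str, str]]] = []
    for d, runs in enumerate(cleaned):
        wc = Counter(tok for run in runs for tok in run if tok in vocab)
        for w, c in wc.items():
            u_rows.append(d)
            u_cols.append(vocab.index[w])
            u_vals.append(c)
        per_doc_bigrams.append(extract_bigrams(runs, vocab))
    bigrams = BigramVocabulary(sorted(set().union(*per_doc_bigrams)))
    s_rows: list[int] = []
    s_cols: list[int] = []
    s_vals: list[int] = []
    for d, bc in enumerate(per_doc_bigrams):
        for pair, c in bc.items():
            s_rows.append(bigrams.index[pair])
            s_cols.append(d)
            s_vals.append(c)
    U = sparse.csr_matrix(
        (np.asarray(u_vals, dtype=np.int64), (u_rows, u_cols)), shape=(nd, nw)
    )
    S = sparse.csr_matrix(
        (np.asarray(s_vals, dtype=np.int64), (s_rows, s_cols)),
        shape=(len(bigrams), nd),
    )
    return U, S, bigrams


@dataclass
class PreparedCorpus:
    """Everything downstream stages need: retained docs, vocabularies, U, S."""

    documents: list[Document]
    runs: list[TokenRuns]
    vocab: Vocabulary
    bigrams: BigramVocabulary
    U: sparse.csr_matrix
    S: sparse.csr_matrix

    @property
    def n_docs(self) -> int:
        return len(self.documents)


def prepare_corpus(
    corpus: Sequence[Document],
    stopwords: Iterable[str] | None = None,
    *,
    min_rate: float = 1e-6,
    min_doc_words: int = 10,
    date_predicate=None,
    **clean_kwargs,
) -> PreparedCorpus:
    """Run the full preparation pipeline: clean, vocab, filter, count tables.

    ``date_predicate`` is an optional callable on ``Document.date`` applied
    before any text processing (e.g. to exclude documents predating a cutoff).
    """
    if date_predicate is not None:
        corpus = [d for d in corpus if date_predicate(d.date)]
    if not corpus:
        raise ValueError("empty corpus (after date filtering)")
    cleaned = [clean_text(d.text, stopwords, **clean_kwargs) for d in corpus]
    vocab = build_vocabulary(cleaned, min_rate=min_rate)
    docs, runs = filter_documents(corpus, vocab, cleaned, min_doc_words=min_doc_words)
    U, S, bigrams = build_count_tables(runs, vocab)
    return PreparedCorpus(docs, runs, vocab, bigrams, U, S)
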
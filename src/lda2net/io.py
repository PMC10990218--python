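"""Reading corpora and writing pipeline artifacts in standard formats.

Corpora come in as plain text (one document per line), CSV (id,text[,date])
or JSONL ({"id": ..., "text": ..., "date": ...}). Count tables go out as
MatrixMarket (MTX) with TSV index files; networks as GraphML, GEXF and
edge-list CSV; matrices and metric tables as CSV.
"""

from __future__ import annotations

import json
from datetime import date as _date
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .corpus_prep import BigramVocabulary, Document, PreparedCorpus, Vocabulary
from .enrichment_core import TopicNetwork

__all__ = [
    "read_corpus",
    "write_corpus_jsonl",
    "write_prepared",
    "read_prepared",
    "write_matrices",
    "read_matrices",
    "write_network",
    "read_network",
]


def _parse_date(value) -> _date | None:
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    return _date.fromisoformat(str(value))


def read_corpus(path: str | Path, fmt: str | None = None) -> list[Document]:
    """Load documents from TXT (one per line), CSV or JSONL, by extension."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt in ("jsonl", "ndjson"):
        docs = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    docs.append(
                        Document(
                            id=str(rec["id"]),
                            text=rec["text"],
                            date=_parse_date(rec.get("date")),
                        )
                    )
        return docs
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"id": str})
        has_date = "date" in df.columns
        return [
            Document(
                id=str(r["id"]),
                text=str(r["text"]),
                date=_parse_date(r["date"]) if has_date else None,
            )
            for _, r in df.iterrows()
        ]
    if fmt == "txt":
        with open(path) as fh:
            return [
                Document(id=f"line{i}", text=line.rstrip("\n"))
                for i, line in enumerate(fh)
                if line.strip()
            ]
    raise ValueError(f"unrecognized corpus format: {fmt!r}")


def write_corpus_jsonl(docs: list[Document], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in docs:
            rec = {"id": d.id, "text": d.text}
            if d.date is not None:
                rec["date"] = d.date.isoformat()
            fh.write(json.dumps(rec) + "\n")


def write_prepared(prep: PreparedCorpus, out_dir: str | Path) -> None:
    """Write U, S (MTX), vocabulary/bigram TSV indexes and doc ids."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "U.mtx", prep.U)
    spio.mmwrite(out / "S.mtx", prep.S)
    word_counts = np.asarray(prep.U.sum(axis=0)).ravel()
    pd.DataFrame(
        {"index": range(len(prep.vocab)), "word": prep.vocab.words, "count": word_counts}
    ).to_csv(out / "vocabulary.tsv", sep="\t", index=False)
    bigram_counts = np.asarray(prep.S.sum(axis=1)).ravel()
    pd.DataFrame(
        {
            "index": range(len(prep.bigrams)),
            "word1": [b[0] for b in prep.bigrams],
            "word2": [b[1] for b in prep.bigrams],
            "count": bigram_counts,
        }
    ).to_csv(out / "bigrams.tsv", sep="\t", index=False)
    (out / "doc_ids.txt").write_text("".join(d.id + "\n" for d in prep.documents))


def read_prepared(out_dir: str | Path) -> PreparedCorpus:
    """Reload a prepared-corpus directory (documents carry ids only)."""
    out = Path(out_dir)
    U = sparse.csr_matrix(spio.mmread(out / "U.mtx"))
    S = sparse.csr_matrix(spio.mmread(out / "S.mtx"))
    vocab_df = pd.read_csv(out / "vocabulary.tsv", sep="\t")
    vocab = Vocabulary(vocab_df["word"].astype(str))
    big_df = pd.read_csv(out / "bigrams.tsv", sep="\t")
    bigrams = BigramVocabulary(
        zip(big_df["word1"].astype(str), big_df["word2"].astype(str))
    )
    doc_ids = (out / "doc_ids.txt").read_text().splitlines()
    docs = [Document(id=i, text="") for i in doc_ids]
    return PreparedCorpus(docs, [], vocab, bigrams, U, S)


def write_matrices(M: np.ndarray, Q: np.ndarray, vocab: Vocabulary, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(M, columns=vocab.words).to_csv(out / "M.csv")
    pd.DataFrame(Q, columns=[f"topic{k}" for k in range(Q.shape[1])]).to_csv(out / "Q.csv")


def read_matrices(out_dir: str | Path, vocab: Vocabulary | None = None):
    from .topic_model_adapter import load_topic_model

    out = Path(out_dir)
    return load_topic_model(out / "M.csv", out / "Q.csv", vocab)


def write_network(net: TopicNetwork, out_dir: str | Path, *, gexf: bool = False) -> None:
    """Write one topic network as edge-list CSV and GraphML (optionally GEXF)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"topic{net.topic_id:03d}"
    rows = [(s, t, w, net.topic_id) for s, t, w in net.edges()]
    pd.DataFrame(rows, columns=["source", "target", "weight", "topic"]).to_csv(
        out / f"{stem}_edges.csv", index=False
    )
    G = net.to_networkx()
    nx.write_graphml(G, out / f"{stem}.graphml")
    if gexf:
        nx.write_gexf(G, out / f"{stem}.gexf")


def read_network(
    path: str | Path, vocab: Vocabulary, topic_id: int, normalized: bool = True
) -> TopicNetwork:
    """Rebuild a TopicNetwork from an edge-list CSV over a known vocabulary."""
    df = pd.read_csv(path)
    nw = len(vocab)
    rows = [vocab.index[w] for w in df["source"].astype(str)]
    cols = [vocab.index[w] for w in df["target"].astype(str)]
    A = sparse.csr_matrix(
        (df["weight"].to_numpy(dtype=float), (rows, cols)), shape=(nw, nw)
    )
    return TopicNetwork(topic_id=topic_id, adjacency=A, vocab=vocab, normalized=normalized)
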
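"""Three-view document index and combined-score ranking.

Every document is embedded three times: its header (title + variants), its
preprocessed body, and its top TF-IDF n-gram features joined into one text.
A query is preprocessed once, embedded once, and scored against every
document as

    S_i = H_{q,i} + B_{q,i} + beta * T_{q,i}

where H, B, T are the cosine similarities between the query vector and the
document's header, body and feature vectors, and ``beta`` weights how much
exact corpus-term (TF-IDF) matching counts relative to semantic matching.
Documents are returned sorted by score, ties broken by document id.

Query-side work is linear in the number of query words: one pass to
preprocess and embed, then one scoring pass over the index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus_model import Corpus, header_text
from .embedding_backend import EmbeddingBackend
from .text_processing import (
    AbbreviationTable,
    lemmatize,
    preprocess_query,
    tokenize_and_clean,
)
from .tfidf_features import TfidfModel, feature_text, top_features

__all__ = [
    "DocumentIndexEntry",
    "DocumentIndex",
    "RankerConfig",
    "SearchResult",
    "UnsearchableQueryError",
    "cosine_similarity",
    "build_index",
    "score_document",
    "search",
    "save_index",
    "load_index",
]


class UnsearchableQueryError(ValueError):
    """Raised when a query has no embeddable tokens after preprocessing.

    Surfaced as an error rather than an empty result list: silently
    returning nothing is a retrieval failure mode worth catching."""


@dataclass(frozen=True)
class RankerConfig:
    """Ranking hyperparameters.

    ``beta`` is the TF-IDF weight in S = H + B + beta*T (default 1.0, i.e.
    the three views count equally); raise it to emphasize exact corpus-term
    matching over semantic matching for low-distractor queries.
    """

    beta: float = 1.0
    top_k: int = 10
    lemmatize_query: bool = False
    case_sensitive_abbrev: bool = True

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class DocumentIndexEntry:
    """The three embedded views of one document."""

    doc_id: str
    header_vec: np.ndarray
    body_vec: np.ndarray
    tfidf_vec: np.ndarray


@dataclass(frozen=True)
class DocumentIndex:
    """One entry per corpus document plus build provenance."""

    entries: dict[str, DocumentIndexEntry]
    backend: EmbeddingBackend
    tfidf_model: TfidfModel
    k: int = 50

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SearchResult:
    """A ranked hit: document id, combined score and its three cosines."""

    doc_id: str
    score: float
    rank: int
    components: tuple[float, float, float]  # (H, B, T)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u·v / (‖u‖‖v‖); defined as 0.0 when either vector is zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def build_index(
    corpus: Corpus,
    backend: EmbeddingBackend,
    tfidf: TfidfModel,
    k: int = 50,
    stopwords: Iterable[str] | None = None,
    lemmatize_docs: bool = True,
) -> DocumentIndex:
    """Embed header, preprocessed body and top-k TF-IDF features per document.

    Deterministic for a deterministic backend: rebuilding with the same
    corpus, backend and configuration reproduces the index bit-for-bit.
    """
    entries: dict[str, DocumentIndexEntry] = {}
    for doc in corpus:
        body_tokens = tokenize_and_clean(doc.body, stopwords)
        if lemmatize_docs:
            body_tokens = lemmatize(body_tokens)
        entries[doc.doc_id] = DocumentIndexEntry(
            doc_id=doc.doc_id,
            header_vec=backend.embed(header_text(doc)),
            body_vec=backend.embed(" ".join(body_tokens)),
            tfidf_vec=backend.embed(feature_text(top_features(tfidf, doc, k))),
        )
    return DocumentIndex(entries=entries, backend=backend, tfidf_model=tfidf, k=k)


def score_document(
    query_vec: np.ndarray, entry: DocumentIndexEntry, beta: float
) -> float:
    """S = H + B + beta*T for one document."""
    h = cosine_similarity(query_vec, entry.header_vec)
    b = cosine_similarity(query_vec, entry.body_vec)
    t = cosine_similarity(query_vec, entry.tfidf_vec)
    return h + b + beta * t


def search(
    query: str,
    index: DocumentIndex,
    config: RankerConfig = RankerConfig(),
    abbrev: AbbreviationTable | None = None,
    stopwords: Iterable[str] | None = None,
) -> list[SearchResult]:
    """Rank all indexed documents for a free-text query; return the top k.

    The query is preprocessed (abbreviation expansion, tokenization,
    cleaning, optional lemmatization), embedded once, and scored against
    every document. Ties are broken by ascending document id. A query that
    reduces to zero embeddable tokens raises
    :class:`UnsearchableQueryError`.
    """
    tokens = preprocess_query(
        query,
        table=abbrev,
        stopwords=stopwords,
        lemmatize_tokens=config.lemmatize_query,
        case_sensitive=config.case_sensitive_abbrev,
    )
    query_vec = index.backend.embed(" ".join(tokens))
    if not tokens or not np.any(query_vec):
        raise UnsearchableQueryError(
            f"query has no embeddable tokens after preprocessing: {query!r}"
        )
    scored: list[SearchResult] = []
    for doc_id in sorted(index.entries):
        entry = index.entries[doc_id]
        h = cosine_similarity(query_vec, entry.header_vec)
        b = cosine_similarity(query_vec, entry.body_vec)
        t = cosine_similarity(query_vec, entry.tfidf_vec)
        scored.append(
            SearchResult(
                doc_id=doc_id,
                score=h + b + config.beta * t,
                rank=0,
                components=(h, b, t),
            )
        )
    scored.sort(key=lambda r: (-r.score, r.doc_id))
    return [
        SearchResult(r.doc_id, r.score, i + 1, r.components)
        for i, r in enumerate(scored[: config.top_k])
    ]


def save_index(index: DocumentIndex, path: str | Path) -> None:
    """Persist the embedded views as JSON (backend recorded by name)."""
    payload = {
        "backend": index.backend.name,
        "dimension": index.backend.dimension,
        "k": index.k,
        "entries": {
            doc_id: {
                "header_vec": e.header_vec.tolist(),
                "body_vec": e.body_vec.tolist(),
                "tfidf_vec": e.tfidf_vec.tolist(),
            }
            for doc_id, e in index.entries.items()
        },
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_index(
    path: str | Path,
    backend: EmbeddingBackend,
    tfidf_model: TfidfModel | None = None,
) -> DocumentIndex:
    """Load a persisted index; the embedding backend is supplied by the
    caller and must match the one the index was built with."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload["dimension"] != backend.dimension:
        raise ValueError(
            f"index dimension {payload['dimension']} != backend dimension "
            f"{backend.dimension}"
        )
    entries = {
        doc_id: DocumentIndexEntry(
            doc_id=doc_id,
            header_vec=np.asarray(rec["header_vec"]),
            body_vec=np.asarray(rec["body_vec"]),
            tfidf_vec=np.asarray(rec["tfidf_vec"]),
        )
        for doc_id, rec in payload["entries"].items()
    }
    return DocumentIndex(
        entries=entries, backend=backend, tfidf_model=tfidf_model, k=payload["k"]
    )
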
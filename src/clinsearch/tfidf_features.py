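"""TF-IDF n-gram features over the corpus.

A term-frequency–inverse-document-frequency model is fitted on the *raw*
(cleaned but unlemmatized) document bodies over unigrams, bigrams and
trigrams. The exact variant is pinned so indexes are reproducible
bit-for-bit:

    idf(t) = ln((1 + N) / (1 + df_t)) + 1          (smoothed idf)
    w(t, d) = tf(t, d) * idf(t), per-document vectors L2-normalized

with raw term counts (no sublinear scaling). This is the standard
default of scikit-learn's ``TfidfVectorizer``, which backs the fit.

Each document's ``k`` highest-weight n-grams (default 50) form its
*feature set*; joined into one text, they are embedded as the document's
third ("T") view alongside header and body.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus_model import Corpus, CorpusError, TopicDocument
from .text_processing import tokenize_and_clean

__all__ = [
    "TfidfModel",
    "FeatureSet",
    "fit_tfidf",
    "top_features",
    "feature_text",
    "save_tfidf_model",
    "load_tfidf_model",
]


def _build_vectorizer(vocabulary: dict[str, int] | None = None) -> TfidfVectorizer:
    return TfidfVectorizer(
        tokenizer=tokenize_and_clean,
        preprocessor=lambda x: x,
        token_pattern=None,
        lowercase=False,
        ngram_range=(1, 3),
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
        vocabulary=vocabulary,
    )


@dataclass
class TfidfModel:
    """Fitted n-gram vocabulary with smoothed-idf weights.

    ``vocabulary`` maps each n-gram (space-joined tokens, n in 1..3) to a
    dense column index; ``idf`` is aligned to those indices. ``doc_ids``
    records which documents the model was fitted on.
    """

    vocabulary: dict[str, int]
    idf: np.ndarray
    n_documents: int
    doc_ids: tuple[str, ...]
    _vectorizer: TfidfVectorizer = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        self.idf = np.asarray(self.idf, dtype=float)
        if self.idf.shape != (len(self.vocabulary),):
            raise ValueError("idf length must match vocabulary size")
        if np.any(self.idf < 1.0 - 1e-12):
            raise ValueError("smoothed idf weights must all be >= 1")
        if self._vectorizer is None:
            vec = _build_vectorizer(self.vocabulary)
            vec.fit(["placeholder"])  # materializes vocabulary_; idf overridden next
            vec.idf_ = self.idf
            self._vectorizer = vec

    @property
    def feature_names(self) -> list[str]:
        names = [""] * len(self.vocabulary)
        for term, idx in self.vocabulary.items():
            names[idx] = term
        return names

    def transform(self, text: str) -> np.ndarray:
        """L2-normalized tf·idf weight vector for one text."""
        return self._vectorizer.transform([text]).toarray()[0]


@dataclass(frozen=True)
class FeatureSet:
    """A document's top-weighted n-grams, descending weight.

    Length is ``min(k, nnz)``; exact weight ties are broken
    lexicographically by n-gram for determinism.
    """

    doc_id: str
    features: tuple[tuple[str, float], ...]
    k: int


def fit_tfidf(corpus: Corpus) -> TfidfModel:
    """Fit the pinned TF-IDF variant on the raw bodies of ``corpus``.

    Requires at least 2 documents (idf is meaningless on one) and nonempty
    bodies throughout.
    """
    if len(corpus) < 2:
        raise CorpusError("TF-IDF fitting requires a corpus of >= 2 documents")
    vectorizer = _build_vectorizer()
    matrix = vectorizer.fit_transform([d.body for d in corpus])
    if matrix.shape[1] == 0:
        raise CorpusError("corpus bodies contain no indexable terms")
    return TfidfModel(
        vocabulary={t: int(i) for t, i in vectorizer.vocabulary_.items()},
        idf=vectorizer.idf_,
        n_documents=len(corpus),
        doc_ids=corpus.doc_ids,
        _vectorizer=vectorizer,
    )


def top_features(model: TfidfModel, doc: TopicDocument, k: int = 50) -> FeatureSet:
    """The ``k`` highest tf·idf-weight n-grams of ``doc``, descending.

    ``doc`` must belong to the fitted corpus; ties in weight are broken
    lexicographically by n-gram.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if doc.doc_id not in model.doc_ids:
        raise KeyError(f"document {doc.doc_id!r} is not in the fitted corpus")
    weights = model.transform(doc.body)
    names = model.feature_names
    nonzero = [(names[i], float(weights[i])) for i in np.nonzero(weights)[0]]
    nonzero.sort(key=lambda pair: (-pair[1], pair[0]))
    return FeatureSet(doc_id=doc.doc_id, features=tuple(nonzero[:k]), k=k)


def feature_text(fs: FeatureSet) -> str:
    """The feature n-grams joined by single spaces in rank order.

    Empty feature sets yield ``""`` (embedded downstream as the zero
    vector).
    """
    return " ".join(term for term, _ in fs.features)


def save_tfidf_model(model: TfidfModel, path: str | Path) -> None:
    """Persist vocabulary, idf weights and fit metadata as JSON."""
    payload = {
        "vocabulary": model.vocabulary,
        "idf": model.idf.tolist(),
        "n_documents": model.n_documents,
        "doc_ids": list(model.doc_ids),
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_tfidf_model(path: str | Path) -> TfidfModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return TfidfModel(
        vocabulary=payload["vocabulary"],
        idf=np.asarray(payload["idf"]),
        n_documents=payload["n_documents"],
        doc_ids=tuple(payload["doc_ids"]),
    )
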
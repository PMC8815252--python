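"""Shared fixtures: tiny hand-checkable corpora and the default synthetic
benchmark (generated once per session)."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from clinsearch import (
    Corpus,
    FixtureSpec,
    TopicDocument,
    build_index,
    fit_tfidf,
    generate_corpus,
    generate_query_set,
    make_toy_backend,
)


@pytest.fixture
def two_doc_corpus() -> Corpus:
    """The hand-evaluated smoothed-idf toy corpus."""
    return Corpus(
        (
            TopicDocument("d1", "Kidney Stones", (), "kidney stone pain"),
            TopicDocument("d2", "Chest Pain", (), "chest pain"),
        )
    )


@pytest.fixture
def three_doc_corpus() -> Corpus:
    """Three documents with disjoint 5-token vocabularies and fixed tags,
    used wherever rankings must be analytically predictable."""
    return Corpus(
        (
            TopicDocument(
                "A", "a1 a2", (), "a1 a2 a3 a4 a5", frozenset({"trauma"})
            ),
            TopicDocument(
                "B", "b1 b2", (), "b1 b2 b3 b4 b5", frozenset({"neoplasm"})
            ),
            TopicDocument(
                "C",
                "c1 c2",
                (),
                "c1 c2 c3 c4 c5",
                frozenset({"trauma", "neoplasm", "surgical"}),
            ),
        )
    )


@pytest.fixture(scope="session")
def default_benchmark():
    """The default synthetic benchmark: corpus, synonym table, index and
    both query sets at the default spec (50 documents)."""
    spec = FixtureSpec()
    corpus, synonyms = generate_corpus(spec)
    backend = make_toy_backend(dimension=64, seed=0, synonym_table=synonyms)
    tfidf = fit_tfidf(corpus)
    index = build_index(corpus, backend, tfidf)
    simple = generate_query_set(corpus, spec, "simple", synonyms)
    complex_ = generate_query_set(corpus, spec, "complex", synonyms)
    return {
        "spec": spec,
        "corpus": corpus,
        "synonyms": synonyms,
        "backend": backend,
        "tfidf": tfidf,
        "index": index,
        "simple": simple,
        "complex": complex_,
    }
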
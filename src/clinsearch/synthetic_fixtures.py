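"""Seed-deterministic synthetic corpora and benchmark query sets.

The generator emulates the measurable structure of a simulated
indication benchmark over a guideline corpus:

* documents with largely disjoint core vocabularies (pseudo-words), short
  titles, synonym-built title variants, bodies of 50–200 tokens, and 1–3
  tags from the default seven-tag vocabulary;
* one *simple* and one *complex* query per document. Simple queries are
  built mostly from title keywords (target: ~32% of query words are title
  keywords) and carry no distractors. Complex queries swap title keywords
  for synonyms and inject distractor phrases — ages in text form, less
  relevant medical and social history — so that only ~9% of their words
  are title keywords, and every complex query carries at least one
  distractor;
* a synonym table linking variant wording to body wording (consumed by
  the toy embedding backend) and an abbreviation table over corpus terms.

Keyword-overlap targets are hit by rejection sampling: a query is
regenerated until its overlap falls inside the target band. Distractor
phrase pools live in ``data/distractors.json`` and are editable without
code changes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np

from .corpus_model import DEFAULT_TAGS, Corpus, TopicDocument
from .evaluation import AnnotatedQuery
from .text_processing import DEFAULT_STOPWORDS, AbbreviationTable

__all__ = [
    "FixtureSpec",
    "generate_corpus",
    "generate_query_set",
    "generate_abbreviation_table",
    "title_keyword_overlap",
    "mean_title_keyword_overlap",
]

_WORD_RE = re.compile(r"[a-z0-9]+(?:[/'-][a-z0-9]+)*")

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"

_CATEGORIES = (
    "breast",
    "cardiac",
    "gastrointestinal",
    "gynecologic",
    "major trauma",
    "musculoskeletal",
    "neurologic",
    "pediatric",
    "thoracic",
    "urologic",
    "vascular",
    "interventional",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic benchmark.

    ``distractor_rates`` gives the injection probability per distractor
    type for complex queries (synonym substitution is always applied, so
    every complex query has at least one distractor regardless);
    ``target_keyword_overlap`` is the (simple, complex) fraction of query
    words that should be title keywords, with ``overlap_tolerance`` the
    accepted half-width per query.
    """

    n_docs: int = 50
    vocabulary_size: int = 1500
    core_tokens_per_doc: int = 12
    tags_per_doc: tuple[int, int] = (1, 3)
    body_length: tuple[int, int] = (50, 200)
    seed: int = 42
    distractor_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.8,
            "medical_history": 0.6,
            "social_history": 0.4,
        }
    )
    target_keyword_overlap: tuple[float, float] = (0.32, 0.09)
    overlap_tolerance: tuple[float, float] = (0.08, 0.04)

    def __post_init__(self) -> None:
        if not all(0.0 <= p <= 1.0 for p in self.distractor_rates.values()):
            raise ValueError("distractor rates must be probabilities")
        object.__setattr__(self, "distractor_rates", dict(self.distractor_rates))


def _load_distractor_pools() -> dict[str, list[str]]:
    with resources.files("clinsearch.data").joinpath("distractors.json").open(
        encoding="utf-8"
    ) as fh:
        return json.load(fh)


def _pseudo_word(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(2, 5))
    syllables = [
        _CONSONANTS[rng.integers(len(_CONSONANTS))]
        + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syll)
    ]
    return "".join(syllables)


def _word_pool(rng: np.random.Generator, size: int) -> list[str]:
    pool: list[str] = []
    seen: set[str] = set(DEFAULT_STOPWORDS)
    while len(pool) < size:
        w = _pseudo_word(rng)
        if w not in seen:
            seen.add(w)
            pool.append(w)
    return pool


def generate_corpus(spec: FixtureSpec = FixtureSpec()) -> tuple[Corpus, dict[str, str]]:
    """Generate a corpus plus the synonym table linking variants to bodies.

    Core vocabularies are disjoint across documents by construction (the
    word pool is partitioned). The returned synonym table maps each
    synonym word to the core token it stands for, so a toy embedding
    backend canonicalizes them to identical vectors.
    """
    core_needed = spec.n_docs * spec.core_tokens_per_doc
    syn_per_doc = 3  # one synonym per title token
    if core_needed + spec.n_docs * syn_per_doc > spec.vocabulary_size:
        raise ValueError(
            "vocabulary too small for disjoint per-document vocabularies: "
            f"need >= {core_needed + spec.n_docs * syn_per_doc}, "
            f"have {spec.vocabulary_size}"
        )
    rng = np.random.default_rng([spec.seed, 0])
    pool = _word_pool(rng, spec.vocabulary_size)
    glue = pool[:15]  # shared low-content tokens, common to all bodies
    cursor = 15

    documents: list[TopicDocument] = []
    synonym_table: dict[str, str] = {}
    tags = sorted(DEFAULT_TAGS)
    for i in range(spec.n_docs):
        core = pool[cursor : cursor + spec.core_tokens_per_doc]
        cursor += spec.core_tokens_per_doc
        title_tokens = core[:3]
        synonyms = pool[cursor : cursor + syn_per_doc]
        cursor += syn_per_doc
        for syn, canonical in zip(synonyms, title_tokens):
            synonym_table[syn] = canonical

        n_variants = int(rng.integers(0, 4))
        variants = []
        for _ in range(n_variants):
            swap = int(rng.integers(3))
            var_tokens = list(title_tokens)
            var_tokens[swap] = synonyms[swap]
            variants.append(" ".join(var_tokens))

        n_body = int(rng.integers(spec.body_length[0], spec.body_length[1] + 1))
        body_tokens = [
            core[rng.integers(len(core))]
            if rng.random() < 0.9
            else glue[rng.integers(len(glue))]
            for _ in range(n_body)
        ]
        n_tags = int(rng.integers(spec.tags_per_doc[0], spec.tags_per_doc[1] + 1))
        doc_tags = frozenset(rng.choice(tags, size=n_tags, replace=False).tolist())

        documents.append(
            TopicDocument(
                doc_id=f"doc{i:03d}",
                title=" ".join(title_tokens).title(),
                variants=tuple(variants),
                body=" ".join(body_tokens),
                tags=doc_tags,
                category=_CATEGORIES[i % len(_CATEGORIES)],
            )
        )
    return Corpus(documents=tuple(documents)), synonym_table


def title_keyword_overlap(query_text: str, title: str) -> float:
    """Fraction of query words that are keywords from the document title."""
    q_tokens = _WORD_RE.findall(query_text.lower())
    t_tokens = set(_WORD_RE.findall(title.lower()))
    if not q_tokens:
        return 0.0
    return sum(t in t_tokens for t in q_tokens) / len(q_tokens)


def mean_title_keyword_overlap(
    queries: Sequence[AnnotatedQuery], corpus: Corpus
) -> float:
    """Mean title-keyword overlap of queries against their ground truths."""
    values = [
        title_keyword_overlap(q.query_text, corpus[q.ground_truth_ids[0]].title)
        for q in queries
        if q.ground_truth_ids
    ]
    return float(np.mean(values))


def _compose(rng: np.random.Generator, units: list[str]) -> str:
    order = rng.permutation(len(units))
    return " ".join(units[i] for i in order)


def _core_fillers(doc: TopicDocument, glue: set[str]) -> list[str]:
    """Non-title content words of the document's own body (glue excluded)."""
    title_tokens = set(doc.title.lower().split())
    return sorted(set(_WORD_RE.findall(doc.body.lower())) - title_tokens - glue)


def _simple_query(
    rng: np.random.Generator,
    doc: TopicDocument,
    spec: FixtureSpec,
    glue: set[str],
) -> str:
    title_tokens = doc.title.lower().split()
    body_fillers = _core_fillers(doc, glue)
    target, tol = spec.target_keyword_overlap[0], spec.overlap_tolerance[0]
    for _ in range(1000):
        n_kw = int(rng.integers(2, 4))
        kws = [title_tokens[j] for j in rng.choice(3, size=min(n_kw, 3), replace=False)]
        n_fill = int(rng.integers(3, 8))
        fillers = [body_fillers[j] for j in rng.integers(len(body_fillers), size=n_fill)]
        text = _compose(rng, kws + fillers)
        if abs(title_keyword_overlap(text, doc.title) - target) <= tol:
            return text
    raise RuntimeError("could not satisfy simple-query overlap target")


def _complex_query(
    rng: np.random.Generator,
    doc: TopicDocument,
    spec: FixtureSpec,
    synonyms_for: dict[str, list[str]],
    pools: dict[str, list[str]],
    glue: set[str],
    other_docs: Sequence[TopicDocument],
) -> tuple[str, tuple[str, ...]]:
    title_tokens = doc.title.lower().split()
    body_fillers = _core_fillers(doc, glue)
    target, tol = spec.target_keyword_overlap[1], spec.overlap_tolerance[1]
    for _ in range(1000):
        # one genuine title keyword; the others replaced by synonyms
        kw_idx = int(rng.integers(3))
        units = [title_tokens[kw_idx]]
        used: list[str] = ["synonym"]
        for j in range(3):
            if j != kw_idx and title_tokens[j] in synonyms_for:
                units.extend(synonyms_for[title_tokens[j]])
        n_fill = int(rng.integers(2, 5))
        units += [body_fillers[j] for j in rng.integers(len(body_fillers), size=n_fill)]
        for dtype, rate in spec.distractor_rates.items():
            if rng.random() >= rate:
                continue
            if dtype == "medical_history":
                # less-relevant history: content words of a *different*
                # document, i.e. conditions that genuinely match other topics
                other = other_docs[rng.integers(len(other_docs))]
                terms = _core_fillers(other, glue)
                n_hx = int(rng.integers(2, 4))
                picked = [terms[j] for j in rng.integers(len(terms), size=n_hx)]
                units.append("history of " + " ".join(picked))
            else:
                units.append(pools_phrase(rng, pools, dtype))
            used.append(dtype)
        text = _compose(rng, units)
        if abs(title_keyword_overlap(text, doc.title) - target) <= tol:
            return text, tuple(dict.fromkeys(used))
    raise RuntimeError("could not satisfy complex-query overlap target")


def pools_phrase(
    rng: np.random.Generator, pools: dict[str, list[str]], dtype: str
) -> str:
    key = "age_templates" if dtype == "age" else dtype
    options = pools[key]
    phrase = options[rng.integers(len(options))]
    return phrase.format(
        age=int(rng.integers(18, 95)),
        py=int(rng.integers(5, 60)),
        n=int(rng.integers(1, 20)),
    )


def generate_query_set(
    corpus: Corpus,
    spec: FixtureSpec,
    mode: Literal["simple", "complex"],
    synonym_table: Mapping[str, str] | None = None,
) -> list[AnnotatedQuery]:
    """One annotated query per document.

    Simple queries contain title keywords and body filler only (no
    distractors); complex queries contain exactly one title keyword,
    synonyms for the rest, body filler, and injected distractor phrases.
    Query tags are copied from the ground-truth document. Deterministic
    given (corpus, spec, mode).
    """
    pools = _load_distractor_pools()
    synonyms_for: dict[str, list[str]] = {}
    for syn, canonical in (synonym_table or {}).items():
        synonyms_for.setdefault(canonical, []).append(syn)
    for v in synonyms_for.values():
        v.sort()
    rng = np.random.default_rng([spec.seed, 1 if mode == "complex" else 2])
    # shared glue tokens are exactly those appearing in more than one body
    # (per-document core vocabularies are disjoint by construction)
    doc_vocab = {d.doc_id: set(_WORD_RE.findall(d.body.lower())) for d in corpus}
    counts: dict[str, int] = {}
    for vocab in doc_vocab.values():
        for t in vocab:
            counts[t] = counts.get(t, 0) + 1
    glue = {t for t, c in counts.items() if c > 1}
    queries: list[AnnotatedQuery] = []
    for doc in corpus:
        if mode == "simple":
            text = _simple_query(rng, doc, spec, glue)
            distractors: tuple[str, ...] = ()
        else:
            others = [d for d in corpus if d.doc_id != doc.doc_id]
            text, distractors = _complex_query(
                rng, doc, spec, synonyms_for, pools, glue, others
            )
        queries.append(
            AnnotatedQuery(
                query_text=text,
                ground_truth_ids=(doc.doc_id,),
                query_tags=doc.tags,
                complexity=mode,
                distractors=distractors,
            )
        )
    return queries


def generate_abbreviation_table(
    corpus: Corpus, n_entries: int = 20, seed: int = 0
) -> AbbreviationTable:
    """Abbreviations (uppercase consonant skeletons) for sampled corpus terms.

    Every expansion is a term occurring in a corpus body; deterministic
    for a fixed seed.
    """
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    rng = np.random.default_rng([seed, 3])
    terms = sorted({t for doc in corpus for t in _WORD_RE.findall(doc.body.lower())})
    chosen = rng.choice(len(terms), size=min(n_entries, len(terms)), replace=False)
    entries: dict[str, tuple[str, ...]] = {}
    for idx in sorted(int(i) for i in chosen):
        term = terms[idx]
        abbrev = "".join(c for c in term if c not in _VOWELS).upper()[:4]
        if not abbrev or abbrev in entries:
            abbrev = term[:2].upper() + str(idx)
        entries[abbrev] = (term,)
    return AbbreviationTable(entries)
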
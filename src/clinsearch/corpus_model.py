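"""Guideline-corpus data model and structured-text I/O.

A corpus is a collection of guideline *topic documents* (e.g. imaging
appropriateness guidelines), each carrying an identifier, a title, a list
of alternate titles ("variants"), the full free-text body, and one or more
category tags used for graded-relevance evaluation.

Two on-disk dialects are supported: a canonical single-file JSON format
(an array of document objects) and a CSV dialect for interoperability
(one row per document; variants and tags semicolon-joined).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_TAGS",
    "TagVocabulary",
    "TopicDocument",
    "Corpus",
    "CorpusError",
    "load_corpus",
    "save_corpus",
    "header_text",
]

#: The seven-tag relevance vocabulary used for graded evaluation.
DEFAULT_TAGS = frozenset(
    {
        "vascular disease",
        "infection/inflammation",
        "neoplasm",
        "congenital",
        "trauma",
        "surgical",
        "many etiologies/topics",
    }
)


class CorpusError(ValueError):
    """Raised when a corpus or document violates a structural invariant."""


@dataclass(frozen=True)
class TagVocabulary:
    """Closed set of category labels documents may be tagged with."""

    labels: frozenset[str] = DEFAULT_TAGS

    def __contains__(self, tag: str) -> bool:
        return tag in self.labels

    def validate(self, tags: Iterable[str]) -> None:
        unknown = sorted(set(tags) - self.labels)
        if unknown:
            raise CorpusError(f"unknown tag(s): {', '.join(unknown)}")


@dataclass(frozen=True)
class TopicDocument:
    """One guideline topic document.

    Parameters
    ----------
    doc_id
        Unique, nonempty identifier within the corpus.
    title
        Document title (nonempty free text).
    variants
        Alternate titles; possibly empty, order preserved.
    body
        Full document text (nonempty).
    tags
        Category labels drawn from the corpus tag vocabulary.
    category
        Optional broad grouping label (e.g. an anatomic section).
    """

    doc_id: str
    title: str
    variants: tuple[str, ...] = ()
    body: str = ""
    tags: frozenset[str] = frozenset()
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("document id must be nonempty")
        if not self.title:
            raise CorpusError(f"document {self.doc_id!r} has an empty title")
        if not self.body:
            raise CorpusError(f"document {self.doc_id!r} has an empty body")
        object.__setattr__(self, "variants", tuple(self.variants))
        object.__setattr__(self, "tags", frozenset(self.tags))


@dataclass(frozen=True)
class Corpus:
    """A validated sequence of topic documents plus their tag vocabulary."""

    documents: tuple[TopicDocument, ...]
    tag_vocabulary: TagVocabulary = field(default_factory=TagVocabulary)

    def __post_init__(self) -> None:
        object.__setattr__(self, "documents", tuple(self.documents))
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusError(f"duplicate document id: {doc.doc_id!r}")
            seen.add(doc.doc_id)
            self.tag_vocabulary.validate(doc.tags)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def __getitem__(self, doc_id: str) -> TopicDocument:
        for doc in self.documents:
            if doc.doc_id == doc_id:
                return doc
        raise KeyError(doc_id)

    @property
    def doc_ids(self) -> tuple[str, ...]:
        return tuple(d.doc_id for d in self.documents)


def header_text(doc: TopicDocument) -> str:
    """Join title and variants into the document *header* text.

    Title first, then variants in order, separated by single spaces.
    Deterministic and never empty for a valid document.
    """
    return " ".join((doc.title, *doc.variants))


def _doc_to_record(doc: TopicDocument) -> dict:
    return {
        "doc_id": doc.doc_id,
        "title": doc.title,
        "variants": list(doc.variants),
        "body": doc.body,
        "tags": sorted(doc.tags),
        "category": doc.category,
    }


def _doc_from_record(rec: dict) -> TopicDocument:
    return TopicDocument(
        doc_id=rec["doc_id"],
        title=rec["title"],
        variants=tuple(rec.get("variants") or ()),
        body=rec["body"],
        tags=frozenset(rec.get("tags") or ()),
        category=rec.get("category") or None,
    )


_CSV_FIELDS = ["doc_id", "title", "variants", "body", "tags", "category"]


def load_corpus(
    path: str | Path,
    format: str = "json",
    tag_vocabulary: TagVocabulary | None = None,
) -> Corpus:
    """Read and validate a corpus from ``path``.

    ``format`` is ``"json"`` (canonical) or ``"csv"``. Unknown tags, duplicate
    ids and empty titles/bodies raise :class:`CorpusError` rather than being
    silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"corpus file not found: {path}")
    vocab = tag_vocabulary or TagVocabulary()
    if format == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(records, list):
            raise CorpusError("corpus JSON must be an array of document objects")
    elif format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        records = [
            {
                "doc_id": row["doc_id"],
                "title": row["title"],
                "variants": [v for v in row["variants"].split(";") if v],
                "body": row["body"],
                "tags": [t for t in row["tags"].split(";") if t],
                "category": row.get("category") or None,
            }
            for row in rows
        ]
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
    docs = tuple(_doc_from_record(rec) for rec in records)
    return Corpus(documents=docs, tag_vocabulary=vocab)


def save_corpus(corpus: Corpus, path: str | Path, format: str = "json") -> None:
    """Write ``corpus`` so that :func:`load_corpus` reproduces it exactly."""
    path = Path(path)
    if format == "json":
        payload = [_doc_to_record(d) for d in corpus]
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    elif format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS, quoting=csv.QUOTE_ALL)
            writer.writeheader()
            for d in corpus:
                writer.writerow(
                    {
                        "doc_id": d.doc_id,
                        "title": d.title,
                        "variants": ";".join(d.variants),
                        "body": d.body,
                        "tags": ";".join(sorted(d.tags)),
                        "category": d.category or "",
                    }
                )
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
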
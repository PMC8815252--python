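"""Sentence-embedding backends.

A backend turns free text into a fixed-length real vector; cosine
similarity between vectors approximates semantic relatedness. Three things
live here:

* the :class:`EmbeddingBackend` contract every backend satisfies
  (pure function of the text, constant dimension, zero vector iff the
  text has no embeddable tokens);
* a deterministic *toy* backend for tests and synthetic benchmarks —
  each token is mapped through a synonym table to a canonical form, the
  canonical form is hashed to a pseudorandom unit vector, and the sentence
  vector is the arithmetic mean of its token vectors (the continuous
  bag-of-words character of large biomedical sentence embedders, at desk
  scale);
* an adapter that loads pretrained word vectors from a word2vec-style
  text file and averages them. Pretrained biomedical models of this
  family typically use dimension 700.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, runtime_checkable

import numpy as np

__all__ = [
    "EmbeddingBackend",
    "ToyEmbeddingBackend",
    "PretrainedTextBackend",
    "make_toy_backend",
    "load_pretrained_backend",
]

_WORD_RE = re.compile(r"[a-z0-9]+(?:[/'-][a-z0-9]+)*")


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract: ``embed`` is a pure function of the input text."""

    dimension: int
    name: str
    deterministic: bool

    def embed(self, text: str) -> np.ndarray: ...


def _token_unit_vector(token: str, dimension: int, seed: int) -> np.ndarray:
    """Stable hash of (token, seed) to a pseudorandom unit vector.

    blake2b is platform-independent, so the same (dimension, seed,
    synonym table) triple yields bit-identical vectors everywhere.
    """
    digest = hashlib.blake2b(
        token.encode("utf-8"), digest_size=8, key=str(seed).encode("utf-8")
    ).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "big"))
    vec = rng.standard_normal(dimension)
    norm = np.linalg.norm(vec)
    return vec / norm


@dataclass(frozen=True)
class ToyEmbeddingBackend:
    """Deterministic token-averaging backend for tests and fixtures.

    Tokens are canonicalized through ``synonym_table`` before hashing, so
    synonym pairs embed identically by construction; unrelated tokens are
    nearly orthogonal at moderate dimension.
    """

    dimension: int = 64
    seed: int = 0
    synonym_table: Mapping[str, str] = field(default_factory=dict)
    name: str = "toy"
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.dimension < 8:
            raise ValueError("toy backend dimension must be >= 8")
        object.__setattr__(self, "synonym_table", dict(self.synonym_table))

    def embed(self, text: str) -> np.ndarray:
        tokens = _WORD_RE.findall(text.lower())
        if not tokens:
            return np.zeros(self.dimension)
        canon = [self.synonym_table.get(t, t) for t in tokens]
        vecs = [_token_unit_vector(t, self.dimension, self.seed) for t in canon]
        return np.mean(vecs, axis=0)


def make_toy_backend(
    dimension: int = 64,
    seed: int = 0,
    synonym_table: Mapping[str, str] | None = None,
) -> ToyEmbeddingBackend:
    """Construct the deterministic toy backend (see class docstring)."""
    return ToyEmbeddingBackend(
        dimension=dimension, seed=seed, synonym_table=synonym_table or {}
    )


@dataclass(frozen=True)
class PretrainedTextBackend:
    """Word-vector averaging over a pretrained text-format model.

    The file format is the word2vec text convention: a header line
    ``<n_tokens> <dimension>`` followed by one ``token v1 ... vdim`` line
    per token. Out-of-vocabulary tokens are skipped; a text with no
    in-vocabulary tokens embeds to the zero vector.
    """

    vectors: Mapping[str, np.ndarray]
    dimension: int
    name: str = "pretrained"
    deterministic: bool = True

    def embed(self, text: str) -> np.ndarray:
        tokens = _WORD_RE.findall(text.lower())
        vecs = [self.vectors[t] for t in tokens if t in self.vectors]
        if not vecs:
            return np.zeros(self.dimension)
        return np.mean(vecs, axis=0)


def load_pretrained_backend(path: str | Path) -> PretrainedTextBackend:
    """Load a word2vec-text-format model file into an embedding backend.

    Raises ``FileNotFoundError`` naming the path if the file is missing and
    ``ValueError`` if the header or any row is malformed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"embedding model file not found: {path}")
    vectors: dict[str, np.ndarray] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"malformed model header in {path}")
        n_tokens, dimension = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dimension + 1:
                raise ValueError(
                    f"malformed vector row in {path}: expected {dimension} values"
                )
            vec = np.asarray([float(x) for x in parts[1:]])
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite vector for token {parts[0]!r} in {path}")
            vectors[parts[0]] = vec
    if len(vectors) != n_tokens:
        raise ValueError(
            f"model header declares {n_tokens} tokens but file has {len(vectors)}"
        )
    return PretrainedTextBackend(vectors=vectors, dimension=dimension)
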
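"""Independent reference implementations used as test oracles.

These deliberately reuse only the low-level primitives of the package
(preprocessing, embedding, single-pair cosine) and recompute rankings and
metrics by direct enumeration, staying independent of the code paths they
check (the vectorized search loop, the NDCG normalization)."""

from __future__ import annotations

import itertools
import math

from clinsearch import preprocess_query, score_document
from clinsearch.ranking_engine import DocumentIndex, RankerConfig


def brute_force_search(
    query: str,
    index: DocumentIndex,
    config: RankerConfig,
    abbrev=None,
    stopwords=None,
) -> list[tuple[str, float]]:
    """Score every document one at a time and sort by (-score, doc_id)."""
    tokens = preprocess_query(
        query,
        table=abbrev,
        stopwords=stopwords,
        lemmatize_tokens=config.lemmatize_query,
        case_sensitive=config.case_sensitive_abbrev,
    )
    qvec = index.backend.embed(" ".join(tokens))
    scored = [
        (doc_id, score_document(qvec, entry, config.beta))
        for doc_id, entry in index.entries.items()
    ]
    scored.sort(key=lambda pair: (-pair[1], pair[0]))
    return scored[: config.top_k]


def dcg(relevances) -> float:
    return sum(rel / math.log2(i + 2) for i, rel in enumerate(relevances))


def max_dcg_over_permutations(relevances) -> float:
    """Ideal DCG by exhaustive enumeration (lists of length <= 6)."""
    return max(dcg(perm) for perm in itertools.permutations(relevances))
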
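"""Retrieval-quality evaluation with tag-graded relevance.

Each query carries ground-truth document id(s) and a set of category tags;
a retrieved document's graded relevance is the number of tags it shares
with the query. Ranking quality is summarized by normalized discounted
cumulative gain over the *full* corpus ranking,

    NDCG = DCG / IDCG,   DCG = sum_i rel_i / log2(i + 1),

where the ideal ordering sorts all corpus relevances descending; plus
top-k accuracy (fraction of queries whose ground truth appears in the
first k results) and mean/sd of the best ground-truth rank. An NDCG of 1
indicates a perfect ranking. When every document has zero relevance to a
query the NDCG is reported as 0.0 with a warning.
"""

from __future__ import annotations

import json
import statistics
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .corpus_model import Corpus, TagVocabulary
from .ranking_engine import (
    DocumentIndex,
    RankerConfig,
    SearchResult,
    UnsearchableQueryError,
    search,
)
from .text_processing import AbbreviationTable

__all__ = [
    "AnnotatedQuery",
    "EvaluationReport",
    "relevance",
    "ndcg",
    "top_k_accuracy",
    "rank_statistics",
    "evaluate",
    "load_query_set",
    "save_query_set",
]


@dataclass(frozen=True)
class AnnotatedQuery:
    """A query with ground truth for evaluation.

    ``ground_truth_ids`` may be empty ("no matching document");
    ``complexity`` distinguishes simple simulated indications, complex
    ones with distractors, and real clinical indications.
    """

    query_text: str
    ground_truth_ids: tuple[str, ...] = ()
    query_tags: frozenset[str] = frozenset()
    complexity: Literal["simple", "complex", "clinical"] = "simple"
    distractors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "ground_truth_ids", tuple(self.ground_truth_ids))
        object.__setattr__(self, "query_tags", frozenset(self.query_tags))
        object.__setattr__(self, "distractors", tuple(self.distractors))


def relevance(
    query_tags: Iterable[str],
    doc_tags: Iterable[str],
    vocabulary: TagVocabulary | None = None,
) -> int:
    """Graded relevance = number of matching tags between query and document."""
    q, d = set(query_tags), set(doc_tags)
    if vocabulary is not None:
        vocabulary.validate(q)
        vocabulary.validate(d)
    return len(q & d)


def ndcg(
    result_relevances: Sequence[int],
    all_relevances: Sequence[int],
) -> float:
    """NDCG of a ranked result list against the ideal corpus-wide ordering.

    ``result_relevances`` is the graded relevance of each result in rank
    order (normally the full corpus ranking; a prefix is allowed and the
    remainder contributes nothing). ``all_relevances`` holds the relevance
    of every corpus document; the ideal DCG sorts it descending. Returns
    0.0 with a ``UserWarning`` when all relevances are zero.
    """
    result = list(result_relevances)
    ideal = sorted(all_relevances, reverse=True)
    if len(result) > len(ideal):
        raise ValueError("more results than corpus documents")
    if Counter(result) - Counter(all_relevances):
        raise ValueError("result relevances are not drawn from all_relevances")
    ranks = np.arange(1, len(ideal) + 1)
    discounts = np.log2(ranks + 1)
    idcg = float(np.sum(np.asarray(ideal) / discounts))
    if idcg == 0.0:
        warnings.warn("all relevances are zero; NDCG reported as 0.0", UserWarning)
        return 0.0
    dcg = float(np.sum(np.asarray(result) / discounts[: len(result)]))
    return dcg / idcg


def top_k_accuracy(
    rankings: Sequence[Sequence[str]],
    ground_truths: Sequence[Iterable[str]],
    k: int,
    mode: Literal["any", "all"] = "any",
) -> tuple[float, int]:
    """Fraction of queries whose ground truth lands in the top ``k``.

    ``mode="any"`` counts a hit when at least one ground-truth id is in
    the top k; ``mode="all"`` requires every ground-truth id there.
    Queries with empty ground truth are excluded from the denominator;
    their count is returned alongside the proportion.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = 0
    scored = 0
    skipped = 0
    for ranking, gt in zip(rankings, ground_truths, strict=True):
        gt = set(gt)
        if not gt:
            skipped += 1
            continue
        scored += 1
        top = set(ranking[:k])
        ok = bool(gt & top) if mode == "any" else gt <= top
        hits += ok
    return (hits / scored if scored else 0.0), skipped


def rank_statistics(
    rankings: Sequence[Sequence[str]],
    ground_truths: Sequence[Iterable[str]],
) -> tuple[float, float, int]:
    """Mean and sd of the best ground-truth rank per query.

    A query whose ground truth is absent from its ranked list is excluded
    from the statistics and counted in the returned flag count.
    """
    best_ranks: list[int] = []
    flagged = 0
    for ranking, gt in zip(rankings, ground_truths, strict=True):
        gt = set(gt)
        positions = [i + 1 for i, doc_id in enumerate(ranking) if doc_id in gt]
        if not positions:
            flagged += 1
            continue
        best_ranks.append(min(positions))
    if not best_ranks:
        return float("nan"), float("nan"), flagged
    mean = statistics.fmean(best_ranks)
    sd = statistics.stdev(best_ranks) if len(best_ranks) > 1 else 0.0
    return mean, sd, flagged


@dataclass
class EvaluationReport:
    """Aggregated retrieval metrics over an annotated query set."""

    n_queries: int
    mean_ndcg: float
    per_query_ndcg: list[float]
    top_k_accuracy: dict[int, float]
    mean_rank: float
    sd_rank: float
    by_complexity: dict[str, dict[str, float]]
    by_category: dict[str, float]
    n_no_ground_truth: int
    n_flagged: int
    n_search_errors: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        out["top_k_accuracy"] = {str(k): v for k, v in self.top_k_accuracy.items()}
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    def table(self) -> str:
        lines = [
            f"queries evaluated      {self.n_queries}",
            f"mean NDCG              {self.mean_ndcg:.3f}",
            f"mean ground-truth rank {self.mean_rank:.2f} ± {self.sd_rank:.2f}",
        ]
        for k in sorted(self.top_k_accuracy):
            lines.append(f"top-{k} accuracy        {self.top_k_accuracy[k]:.3f}")
        for cx, stats in sorted(self.by_complexity.items()):
            lines.append(f"[{cx}] mean NDCG       {stats['mean_ndcg']:.3f}")
        return "\n".join(lines)


def evaluate(
    query_set: Sequence[AnnotatedQuery],
    index: DocumentIndex,
    corpus: Corpus,
    config: RankerConfig = RankerConfig(),
    abbrev: AbbreviationTable | None = None,
    stopwords: Iterable[str] | None = None,
    ks: Sequence[int] = (3, 5, 10),
) -> EvaluationReport:
    """Run the search per query and aggregate NDCG, top-k and rank stats.

    NDCG is computed over the full corpus ranking (top_k is overridden to
    the corpus size internally). Per-query search errors are recorded in
    the report, not fatal. Results are invariant to query order.
    """
    doc_tags = {d.doc_id: d.tags for d in corpus}
    doc_category = {d.doc_id: (d.category or "uncategorized") for d in corpus}
    full_config = RankerConfig(
        beta=config.beta,
        top_k=len(corpus),
        lemmatize_query=config.lemmatize_query,
        case_sensitive_abbrev=config.case_sensitive_abbrev,
    )

    per_query_ndcg: list[float] = []
    rankings: list[list[str]] = []
    ground_truths: list[tuple[str, ...]] = []
    complexities: list[str] = []
    categories: list[str] = []
    n_no_gt = 0
    n_errors = 0
    warn_msgs: list[str] = []

    for query in query_set:
        try:
            results: list[SearchResult] = search(
                query.query_text, index, full_config, abbrev, stopwords
            )
        except UnsearchableQueryError as exc:
            n_errors += 1
            warn_msgs.append(str(exc))
            continue
        ranking = [r.doc_id for r in results]
        rels = [relevance(query.query_tags, doc_tags[doc_id]) for doc_id in ranking]
        all_rels = [
            relevance(query.query_tags, tags) for tags in doc_tags.values()
        ]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            value = ndcg(rels, all_rels)
        warn_msgs.extend(str(w.message) for w in caught)
        per_query_ndcg.append(value)
        rankings.append(ranking)
        ground_truths.append(query.ground_truth_ids)
        complexities.append(query.complexity)
        if query.ground_truth_ids:
            categories.append(doc_category[query.ground_truth_ids[0]])
        else:
            categories.append("no ground truth")
            n_no_gt += 1

    topk: dict[int, float] = {}
    for k in ks:
        topk[k], _ = top_k_accuracy(rankings, ground_truths, k, mode="any")
    mean_rank, sd_rank, flagged = rank_statistics(
        [r for r, g in zip(rankings, ground_truths) if g],
        [g for g in ground_truths if g],
    )

    by_complexity: dict[str, dict[str, float]] = {}
    for cx in sorted(set(complexities)):
        idx = [i for i, c in enumerate(complexities) if c == cx]
        sub_rankings = [rankings[i] for i in idx]
        sub_gts = [ground_truths[i] for i in idx]
        acc3, _ = top_k_accuracy(sub_rankings, sub_gts, 3, mode="any")
        by_complexity[cx] = {
            "mean_ndcg": statistics.fmean(per_query_ndcg[i] for i in idx),
            "top_3_accuracy": acc3,
            "n": float(len(idx)),
        }

    by_category: dict[str, float] = {}
    for cat in sorted(set(categories)):
        idx = [i for i, c in enumerate(categories) if c == cat]
        by_category[cat] = statistics.fmean(per_query_ndcg[i] for i in idx)

    return EvaluationReport(
        n_queries=len(per_query_ndcg),
        mean_ndcg=statistics.fmean(per_query_ndcg) if per_query_ndcg else 0.0,
        per_query_ndcg=per_query_ndcg,
        top_k_accuracy=topk,
        mean_rank=mean_rank,
        sd_rank=sd_rank,
        by_complexity=by_complexity,
        by_category=by_category,
        n_no_ground_truth=n_no_gt,
        n_flagged=flagged,
        n_search_errors=n_errors,
        warnings=warn_msgs,
    )


def load_query_set(path: str | Path) -> list[AnnotatedQuery]:
    """Read a JSON array of annotated-query objects."""
    records = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        AnnotatedQuery(
            query_text=rec["query_text"],
            ground_truth_ids=tuple(rec.get("ground_truth_ids") or ()),
            query_tags=frozenset(rec.get("query_tags") or ()),
            complexity=rec.get("complexity", "simple"),
            distractors=tuple(rec.get("distractors") or ()),
        )
        for rec in records
    ]


def save_query_set(queries: Sequence[AnnotatedQuery], path: str | Path) -> None:
    payload = [
        {
            "query_text": q.query_text,
            "ground_truth_ids": list(q.ground_truth_ids),
            "query_tags": sorted(q.query_tags),
            "complexity": q.complexity,
            "distractors": list(q.distractors),
        }
        for q in queries
    ]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
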
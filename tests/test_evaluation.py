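import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import dcg, max_dcg_over_permutations

from clinsearch import (
    AnnotatedQuery,
    RankerConfig,
    TagVocabulary,
    build_index,
    evaluate,
    fit_tfidf,
    load_query_set,
    make_toy_backend,
    ndcg,
    rank_statistics,
    relevance,
    save_query_set,
    top_k_accuracy,
)

LOG2_3 = math.log2(3)


class TestRelevance:
    @pytest.mark.parametrize(
        "q,d,expected",
        [
            ({"trauma", "vascular disease"}, {"trauma"}, 1),
            ({"trauma"}, {"neoplasm"}, 0),
            ({"trauma", "surgical", "neoplasm"}, {"trauma", "surgical", "neoplasm"}, 3),
        ],
    )
    def test_matching_tag_count(self, q, d, expected):
        assert relevance(q, d) == expected

    def test_unknown_tag_rejected_with_vocabulary(self):
        with pytest.raises(Exception, match="oncology"):
            relevance({"oncology"}, {"trauma"}, vocabulary=TagVocabulary())


class TestNdcg:
    def test_ideal_order_is_one(self):
        assert ndcg([3, 2, 1, 0, 0], [3, 2, 1, 0, 0]) == pytest.approx(1.0)

    def test_hand_evaluated_two_results(self):
        # (0/log2(2) + 1/log2(3)) / (1/log2(2))
        assert ndcg([0, 1], [1, 0]) == pytest.approx(1 / LOG2_3, abs=1e-9)

    def test_all_zero_relevance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert ndcg([0, 0, 0], [0, 0, 0]) == 0.0

    def test_results_must_be_drawn_from_corpus_relevances(self):
        with pytest.raises(ValueError):
            ndcg([5, 0], [1, 0])

    def test_matches_max_over_permutations_oracle_exhaustively(self):
        """Normalization equals brute-force max DCG over all permutations
        for every multiset of grades 0..3 with length <= 6."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 7))
            rels = rng.integers(0, 4, size=n).tolist()
            if not any(rels):
                continue
            perm = rng.permutation(n)
            result = [rels[i] for i in perm]
            expected = dcg(result) / max_dcg_over_permutations(rels)
            assert ndcg(result, rels) == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=12),
        st.randoms(use_true_random=False),
    )
    @settings(deadline=None, max_examples=200)
    def test_bounded_in_unit_interval_for_any_permutation(self, rels, rnd):
        result = list(rels)
        rnd.shuffle(result)
        if not any(rels):
            with pytest.warns(UserWarning):
                assert ndcg(result, rels) == 0.0
        else:
            assert 0.0 <= ndcg(result, rels) <= 1.0 + 1e-12


class TestTopKAccuracy:
    RANKINGS = [["a", "b", "c", "d", "e"], ["b", "c", "d", "e", "a"]]

    def test_any_mode_fraction(self):
        acc, _ = top_k_accuracy(self.RANKINGS, [{"a"}, {"a"}], k=3, mode="any")
        assert acc == 0.5

    def test_all_mode_requires_every_ground_truth(self):
        acc, _ = top_k_accuracy([["x", "a", "y", "b", "z"]], [{"a", "b"}], k=5, mode="all")
        assert acc == 1.0
        acc, _ = top_k_accuracy([["x", "a", "y", "b", "z"]], [{"a", "b"}], k=3, mode="all")
        assert acc == 0.0

    def test_k_at_least_corpus_size_is_perfect(self):
        acc, _ = top_k_accuracy(self.RANKINGS, [{"e"}, {"a"}], k=5)
        assert acc == 1.0

    def test_empty_ground_truth_excluded_and_counted(self):
        acc, skipped = top_k_accuracy(self.RANKINGS, [{"a"}, set()], k=1)
        assert acc == 1.0
        assert skipped == 1

    def test_non_decreasing_in_k(self):
        gts = [{"c"}, {"a"}]
        accs = [top_k_accuracy(self.RANKINGS, gts, k)[0] for k in range(1, 6)]
        assert accs == sorted(accs)


class TestRankStatistics:
    def test_mean_of_best_ranks(self):
        rankings = [["a", "b"], ["a", "b"], ["b", "a"]]
        mean, sd, flagged = rank_statistics(rankings, [{"a"}, {"a"}, {"a"}])
        assert mean == pytest.approx(4 / 3)
        assert flagged == 0

    def test_single_query(self):
        mean, sd, flagged = rank_statistics(
            [["x1", "x2", "x3", "x4", "x5", "x6", "g"]], [{"g"}]
        )
        assert (mean, sd, flagged) == (7.0, 0.0, 0)

    def test_missing_ground_truth_flagged_and_excluded(self):
        mean, sd, flagged = rank_statistics([["a"], ["b"]], [{"a"}, {"z"}])
        assert flagged == 1
        assert mean == 1.0

    def test_multiple_ground_truths_use_best(self):
        mean, _, _ = rank_statistics([["x", "g1", "y", "g2"]], [{"g1", "g2"}])
        assert mean == 2.0


class TestEvaluate:
    """Four hand-scored queries on the disjoint-vocabulary corpus.

    Token-count margins force every ranking analytically, so the report
    is checked against frozen hand-computed numbers:

    q1 "a1 a2 a3 c1"    (GT A, tags {trauma})           -> [A,C,B], rels 1,1,0, NDCG 1
    q2 "a1 a3 a4 b1" (GT A, tags {trauma,neoplasm,
                      surgical})                        -> [A,B,C], rels 1,1,3,
                                                           NDCG = 0.7579237460681981
    q3 "c1 c2 c4 a1"    (GT C, tags of C)               -> [C,A,B], rels 3,1,1, NDCG 1
    q4 "a1 a2 a3 a4 c5" (GT C, tags of C)               -> [A,C,B], rels 1,3,1,
                                                           NDCG = 0.8213137146137828
    """

    Q = [
        AnnotatedQuery("a1 a2 a3 c1", ("A",), frozenset({"trauma"}), "simple"),
        AnnotatedQuery(
            "a1 a3 a4 b1", ("A",),
            frozenset({"trauma", "neoplasm", "surgical"}), "simple",
        ),
        AnnotatedQuery(
            "c1 c2 c4 a1", ("C",),
            frozenset({"trauma", "neoplasm", "surgical"}), "complex",
        ),
        AnnotatedQuery(
            "a1 a2 a3 a4 c5", ("C",),
            frozenset({"trauma", "neoplasm", "surgical"}), "complex",
        ),
    ]

    @pytest.fixture
    def index(self, three_doc_corpus):
        backend = make_toy_backend(256, 0)
        return build_index(three_doc_corpus, backend, fit_tfidf(three_doc_corpus))

    def test_matches_hand_computed_report(self, three_doc_corpus, index):
        report = evaluate(self.Q, index, three_doc_corpus, ks=(1, 3))
        expected_ndcg = [1.0, 0.7579237460681981, 1.0, 0.8213137146137828]
        assert report.n_queries == 4
        assert report.per_query_ndcg == pytest.approx(expected_ndcg, abs=1e-9)
        assert report.mean_ndcg == pytest.approx(sum(expected_ndcg) / 4, abs=1e-9)
        assert report.top_k_accuracy[3] == 1.0
        assert report.top_k_accuracy[1] == 0.75  # q4's GT C ranks 2nd
        assert report.mean_rank == pytest.approx(1.25)
        assert report.n_search_errors == 0

    def test_breakdown_by_complexity(self, three_doc_corpus, index):
        report = evaluate(self.Q, index, three_doc_corpus)
        assert report.by_complexity["simple"]["n"] == 2
        assert report.by_complexity["complex"]["n"] == 2
        assert report.by_complexity["simple"]["mean_ndcg"] == pytest.approx(
            (1.0 + 0.7579237460681981) / 2, abs=1e-9
        )

    def test_invariant_to_query_order(self, three_doc_corpus, index):
        fwd = evaluate(self.Q, index, three_doc_corpus)
        rev = evaluate(list(reversed(self.Q)), index, three_doc_corpus)
        assert sorted(fwd.per_query_ndcg) == pytest.approx(sorted(rev.per_query_ndcg))
        assert fwd.mean_ndcg == pytest.approx(rev.mean_ndcg)
        assert fwd.top_k_accuracy == rev.top_k_accuracy

    def test_unsearchable_query_recorded_not_fatal(self, three_doc_corpus, index):
        queries = [self.Q[0], AnnotatedQuery("the of", ("A",), frozenset({"trauma"}))]
        report = evaluate(queries, index, three_doc_corpus)
        assert report.n_search_errors == 1
        assert report.n_queries == 1

    def test_query_set_json_round_trip(self, tmp_path):
        path = tmp_path / "queries.json"
        save_query_set(self.Q, path)
        assert load_query_set(path) == self.Q


class TestEvaluatePerfectAndAdversarial:
    def test_perfect_search_gives_perfect_report(self, three_doc_corpus):
        backend = make_toy_backend(256, 0)
        index = build_index(three_doc_corpus, backend, fit_tfidf(three_doc_corpus))
        queries = [
            AnnotatedQuery(doc.title + " " + doc.body, (doc.doc_id,), doc.tags)
            for doc in three_doc_corpus
        ]
        report = evaluate(queries, index, three_doc_corpus)
        assert report.top_k_accuracy[3] == 1.0
        assert report.mean_rank == 1.0

    def test_ground_truth_ranked_last_gives_zero_top3(self, three_doc_corpus):
        backend = make_toy_backend(256, 0)
        index = build_index(three_doc_corpus, backend, fit_tfidf(three_doc_corpus))
        # query entirely in A's vocabulary but annotated with GT B: B sits
        # behind A and (by noise) around C, never in the top 1
        queries = [
            AnnotatedQuery("a1 a2 a3 a4", ("B",), frozenset({"neoplasm"})),
        ]
        report = evaluate(queries, index, three_doc_corpus, ks=(1,))
        assert report.top_k_accuracy[1] == 0.0
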
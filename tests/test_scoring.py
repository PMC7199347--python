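"""Correlation-score computation, aggregation, ranking and restriction."""

import random

import pytest

from meshblast.mesh import ArticleRecord, ArticleStore
from meshblast.scoring import (
    QueryTermScores,
    TermSummary,
    aggregate_terms,
    filter_categories,
    score_query,
    top_n,
)


def make_store(articles: dict[int, tuple[set[str], set[str]]]) -> ArticleStore:
    store = ArticleStore()
    for pmid, (major, minor) in articles.items():
        store.add(ArticleRecord(pmid=pmid, journal="J", year=2000,
                                major_terms=frozenset(major),
                                minor_terms=frozenset(minor)))
    return store


class TestScoreQuery:
    def test_three_of_four_articles(self):
        store = make_store({
            1: ({"Apoptosis"}, set()),
            2: ({"Apoptosis"}, set()),
            3: ({"Apoptosis", "Brain"}, set()),
            4: (set(), {"Apoptosis"}),
        })
        qts = score_query({1, 2, 3, 4}, store, "major", query_id="q1")
        assert qts.n_articles == 4
        assert qts.scores["Apoptosis"] == 0.75
        assert qts.scores["Brain"] == 0.25

    def test_single_article_attains_upper_bound(self):
        store = make_store({1: ({"T"}, set())})
        qts = score_query({1}, store, "major")
        assert qts.scores == {"T": 1.0}

    def test_unresolvable_pmids_excluded_from_denominator(self):
        store = make_store({1: ({"T"}, set())})
        qts = score_query({1, 99, 100}, store, "major")
        assert qts.n_articles == 1
        assert qts.scores["T"] == 1.0

    def test_term_free_articles_count_in_denominator(self):
        store = make_store({1: ({"T"}, set()), 2: (set(), set())})
        qts = score_query({1, 2}, store, "major")
        assert qts.scores["T"] == 0.5

    def test_no_resolvable_articles_gives_empty_map(self):
        qts = score_query({1, 2}, make_store({}), "major")
        assert qts.n_articles == 0 and qts.scores == {}

    def test_invalid_facet_rejected(self):
        with pytest.raises(ValueError):
            score_query({1}, make_store({}), "both")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_triple_loop_oracle_on_random_stores(self, seed):
        rnd = random.Random(seed)
        vocab = [f"T{i}" for i in range(10)]
        articles = {}
        for pmid in range(1, rnd.randint(2, 30)):
            major = {t for t in vocab if rnd.random() < 0.3}
            minor = {t for t in vocab if rnd.random() < 0.3} - major
            articles[pmid] = (major, minor)
        store = make_store(articles)
        pmids = {p for p in articles if rnd.random() < 0.8}
        for facet in ("major", "minor"):
            qts = score_query(pmids, store, facet)
            # independent count-and-divide
            expected = {}
            n = len(pmids)
            for term in vocab:
                count = sum(
                    1 for p in pmids
                    if term in articles[p][0 if facet == "major" else 1]
                )
                if count:
                    expected[term] = count / n
            assert qts.scores == expected


class TestAggregate:
    def test_sum_and_support(self):
        per_query = [
            QueryTermScores("q1", "major", {"T": 0.75}, 4),
            QueryTermScores("q2", "major", {"T": 0.5}, 2),
        ]
        (summary,) = aggregate_terms(per_query)
        assert summary.total_score == 1.25
        assert summary.annotated_queries == 2
        assert summary.supporting_queries == {"q1", "q2"}

    def test_empty_input_gives_empty_list(self):
        assert aggregate_terms([]) == []

    def test_mixed_facets_rejected(self):
        with pytest.raises(ValueError):
            aggregate_terms([
                QueryTermScores("q1", "major", {"T": 1.0}, 1),
                QueryTermScores("q2", "minor", {"T": 1.0}, 1),
            ])

    def test_tie_break_by_support_then_name(self):
        per_query = [
            QueryTermScores("q1", "major", {"B": 0.5, "A": 0.5, "C": 1.0}, 2),
            QueryTermScores("q2", "major", {"B": 0.5}, 2),
        ]
        got = aggregate_terms(per_query)
        # B: 1.0 over 2 queries; C: 1.0 over 1 query; A: 0.5 over 1 query
        assert [s.term for s in got] == ["B", "C", "A"]
        # cross-check against an independent re-sort
        resorted = sorted(got, key=lambda s: (-s.total_score,
                                              -s.annotated_queries, s.term))
        assert got == resorted

    def test_permutation_invariance(self):
        rnd = random.Random(42)
        per_query = [
            QueryTermScores(f"q{i}", "major",
                            {t: rnd.choice([0.25, 0.5, 1.0])
                             for t in "ABCDE" if rnd.random() < 0.6}, 4)
            for i in range(8)
        ]
        base = aggregate_terms(per_query)
        for _ in range(5):
            rnd.shuffle(per_query)
            again = aggregate_terms(per_query)
            assert [(s.term, s.annotated_queries) for s in again] == [
                (s.term, s.annotated_queries) for s in base
            ]
            assert all(abs(a.total_score - b.total_score) < 1e-12
                       for a, b in zip(again, base))

    def test_score_bound_invariant(self):
        rnd = random.Random(7)
        per_query = [
            QueryTermScores(f"q{i}", "major",
                            {t: rnd.randint(1, 4) / 4
                             for t in "ABCDEF" if rnd.random() < 0.5}, 4)
            for i in range(20)
        ]
        for s in aggregate_terms(per_query):
            assert 0.0 < s.total_score <= s.annotated_queries + 1e-12


class TestRestriction:
    TREE = {"T_immune": {"A15.145"}, "T_pheno": {"G12.450"},
            "T_other": {"D12.776"}}

    def _summaries(self):
        return [
            TermSummary("T_immune", "major", 2.0, frozenset({"q1", "q2"})),
            TermSummary("T_other", "major", 1.5, frozenset({"q1", "q3"})),
            TermSummary("T_pheno", "major", 0.5, frozenset({"q2"})),
        ]

    def test_exact_restriction(self):
        got = filter_categories(self._summaries(), self.TREE, {"A15", "G12"})
        assert [s.term for s in got] == ["T_immune", "T_pheno"]

    def test_empty_category_set_gives_empty(self):
        assert filter_categories(self._summaries(), self.TREE, set()) == []

    def test_result_is_subsequence(self):
        rnd = random.Random(3)
        for _ in range(20):
            summaries = [
                TermSummary(t, "major", rnd.random() * 3,
                            frozenset({f"q{i}" for i in range(rnd.randint(1, 4))}))
                for t in ("T_immune", "T_pheno", "T_other", "T_unmapped")
            ]
            summaries.sort(key=lambda s: -s.total_score)
            got = filter_categories(summaries, self.TREE, {"A15", "G12"})
            it = iter(summaries)
            assert all(any(s is t for t in it) for s in got)

    def test_restriction_commutes_with_aggregation(self):
        rnd = random.Random(9)
        per_query = [
            QueryTermScores(f"q{i}", "major",
                            {t: rnd.randint(1, 3) / 3
                             for t in self.TREE if rnd.random() < 0.7}, 3)
            for i in range(10)
        ]
        route1 = filter_categories(aggregate_terms(per_query), self.TREE, {"A15"})
        prefiltered = [
            QueryTermScores(q.query_id, q.facet,
                            {t: s for t, s in q.scores.items()
                             if t == "T_immune"}, q.n_articles)
            for q in per_query
        ]
        route2 = aggregate_terms([q for q in prefiltered if q.scores])
        assert [(s.term, s.total_score, s.annotated_queries) for s in route1] == [
            (s.term, s.total_score, s.annotated_queries) for s in route2
        ]


class TestTopN:
    def test_first_n(self):
        summaries = [TermSummary(f"T{i:02d}", "major", 25 - i, frozenset({"q"}))
                     for i in range(25)]
        assert len(top_n(summaries, 20)) == 20
        assert top_n(summaries, 20) == summaries[:20]

    def test_edge_sizes(self):
        summaries = [TermSummary("T", "major", 1.0, frozenset({"q"}))]
        assert top_n(summaries, 0) == []
        assert top_n(summaries, 5) == summaries
        with pytest.raises(ValueError):
            top_n(summaries, -1)
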
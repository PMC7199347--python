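"""The correlation score: per-query normalized MeSH term frequencies.

Heavily studied genes accumulate more articles and hence more MeSH term
occurrences than obscure ones. To remove that popularity effect, each term's
count within a query's article set is divided by the number of that query's
articles, giving a per-query *correlation score* in (0, 1]: the fraction of
the query's linked literature carrying the term. Terms are then ranked
globally by the sum of scores over queries. The scores are descriptive ranks
only — no significance testing is attached to them.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from .mesh import ArticleStore, MeshTreeMap, term_in_categories

__all__ = [
    "QueryTermScores",
    "TermSummary",
    "score_query",
    "aggregate_terms",
    "filter_categories",
    "top_n",
    "write_term_summary_tsv",
    "term_summaries_to_json",
]

logger = logging.getLogger(__name__)

FACETS = ("major", "minor")


@dataclass(frozen=True)
class QueryTermScores:
    """One query's correlation scores over one MeSH facet.

    ``n_articles`` counts the query's deduplicated PMIDs that resolved in the
    article store; each score is (articles containing the term) / n_articles.
    A query with no resolvable articles has an empty score map.
    """

    query_id: str
    facet: str
    scores: dict[str, float]
    n_articles: int


@dataclass(frozen=True)
class TermSummary:
    """A term's global standing: summed score plus supporting evidence.

    Since each per-query score is at most 1, ``total_score`` can never exceed
    ``annotated_queries`` — the structural bound every ranked row obeys.
    """

    term: str
    facet: str
    total_score: float
    supporting_queries: frozenset[str]

    @property
    def annotated_queries(self) -> int:
        return len(self.supporting_queries)


def score_query(
    pmids: Iterable[int], store: ArticleStore, facet: str, query_id: str = ""
) -> QueryTermScores:
    """Score one query's article set over one facet.

    PMIDs absent from the store are excluded from both the term counts and
    the denominator (they contribute no parseable metadata); present articles
    with no headings still count in the denominator.
    """
    if facet not in FACETS:
        raise ValueError(f"facet must be one of {FACETS}, got {facet!r}")
    resolved = []
    unresolved = 0
    for pmid in sorted(set(pmids)):
        record = store.get(pmid)
        if record is None:
            unresolved += 1
        else:
            resolved.append(record)
    if unresolved:
        logger.debug(
            "query %s: %d PMIDs absent from article store", query_id, unresolved
        )
    n = len(resolved)
    if n == 0:
        return QueryTermScores(query_id=query_id, facet=facet, scores={}, n_articles=0)
    counts: Counter[str] = Counter()
    for record in resolved:
        counts.update(record.terms(facet))
    scores = {term: count / n for term, count in counts.items()}
    return QueryTermScores(query_id=query_id, facet=facet, scores=scores, n_articles=n)


def aggregate_terms(per_query: Sequence[QueryTermScores]) -> list[TermSummary]:
    """Sum per-query scores into globally ranked term summaries.

    Sorted by total score descending; ties broken by supporting-query count
    descending, then term name ascending, so output order is deterministic
    under any permutation of the input.
    """
    facets = {qts.facet for qts in per_query}
    if len(facets) > 1:
        raise ValueError(f"mixed facets in input: {sorted(facets)}")
    facet = next(iter(facets)) if facets else "major"

    totals: dict[str, float] = {}
    support: dict[str, set[str]] = {}
    # Accumulate in sorted query order so float summation order is fixed.
    for qts in sorted(per_query, key=lambda q: q.query_id):
        for term, score in qts.scores.items():
            totals[term] = totals.get(term, 0.0) + score
            support.setdefault(term, set()).add(qts.query_id)

    summaries = [
        TermSummary(
            term=term,
            facet=facet,
            total_score=totals[term],
            supporting_queries=frozenset(support[term]),
        )
        for term in totals
    ]
    summaries.sort(key=lambda s: (-s.total_score, -s.annotated_queries, s.term))
    return summaries


def filter_categories(
    summaries: Sequence[TermSummary],
    tree: MeshTreeMap,
    categories: Iterable[str],
) -> list[TermSummary]:
    """Restrict ranked summaries to terms inside the given MeSH categories.

    A pure restriction: relative order and scores are unchanged (no
    re-normalization), so the result is a subsequence of the input.
    """
    categories = list(categories)
    return [s for s in summaries if term_in_categories(s.term, tree, categories)]


def top_n(summaries: Sequence[TermSummary], n: int) -> list[TermSummary]:
    """First ``min(n, len)`` entries of an already ranked list."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return list(summaries[:n])


def write_term_summary_tsv(summaries: Sequence[TermSummary], stream: IO[str]) -> None:
    """Write the ranked term table: term, score (2 decimals), annotated queries.

    Display rounds the score to 2 decimals; full precision lives in the JSON
    evidence bundle.
    """
    stream.write("term\tscore\tannotated_queries\n")
    for s in summaries:
        stream.write(f"{s.term}\t{s.total_score:.2f}\t{s.annotated_queries}\n")


def term_summaries_to_json(summaries: Sequence[TermSummary]) -> list[dict]:
    """Full-precision JSON-ready form, including the supporting query IDs."""
    return [
        {
            "term": s.term,
            "facet": s.facet,
            "total_score": s.total_score,
            "annotated_queries": s.annotated_queries,
            "supporting_queries": sorted(s.supporting_queries),
        }
        for s in summaries
    ]


def term_summaries_from_json(data: Sequence[dict]) -> list[TermSummary]:
    """Inverse of :func:`term_summaries_to_json`."""
    return [
        TermSummary(
            term=d["term"],
            facet=d["facet"],
            total_score=float(d["total_score"]),
            supporting_queries=frozenset(d["supporting_queries"]),
        )
        for d in data
    ]
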
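"""Result-page artifacts: term tables, distributions, depth scans, job IDs.

This module assembles the downstream outputs of an annotation run: the
top-term tables (overall major, overall minor, immune-restricted major),
the evidence-corpus journal distribution, the best-hit taxonomic
distribution, and the hit-depth sensitivity scan that profiles annotation
coverage, mean hit identity, and article/term yield as the per-query hit
cap rises — the diagnostic behind choosing how many BLAST hits to mine for
literature.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from typing import IO, Mapping, Sequence

from .blast_io import AnnotationConfig, HitTable, truncate_depth
from .literature import LinkMap, QueryArticles, collect_query_pmids
from .mesh import ArticleStore, MeshTreeMap
from .scoring import (
    QueryTermScores,
    TermSummary,
    aggregate_terms,
    filter_categories,
    score_query,
    term_summaries_from_json,
    term_summaries_to_json,
    top_n,
    write_term_summary_tsv,
)

__all__ = [
    "DepthProfileRow",
    "DistributionTable",
    "AnnotationResult",
    "DEFAULT_DEPTH_GRID",
    "depth_scan",
    "taxonomic_distribution",
    "journal_distribution",
    "job_id",
    "run_annotation",
    "render_report",
    "load_report_json",
]

#: Default hit-depth grid for the sensitivity scan.
DEFAULT_DEPTH_GRID = (1, 5, 10, 25, 50, 100, 200, 300, 400, 500)


@dataclass(frozen=True)
class DepthProfileRow:
    """Annotation metrics at one hit depth k.

    ``mean_identity_pct`` is None when no hit survives at this depth.
    ``total_mesh_terms`` counts distinct terms (major and minor pooled) over
    the distinct resolvable articles; ``mesh_term_tokens`` counts term
    occurrences (one per article carrying the term) for comparison.
    """

    k: int
    pct_annotated: float
    mean_identity_pct: float | None
    articles_per_annotated_query: float
    total_mesh_terms: int
    total_articles: int
    mesh_term_tokens: int


@dataclass
class DistributionTable:
    """label → positive count, ranked by count descending then label ascending."""

    counts: dict[str, int]

    def items(self) -> list[tuple[str, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def total(self) -> int:
        return sum(self.counts.values())


def depth_scan(
    table: HitTable,
    links: LinkMap,
    store: ArticleStore,
    ks: Sequence[int] = DEFAULT_DEPTH_GRID,
) -> list[DepthProfileRow]:
    """Profile annotation metrics over a grid of per-query hit depths.

    ``table`` must already be filtered; each row recomputes the full
    truncate → link → measure path at one depth, so coverage and article
    counts are non-decreasing in k by construction.
    """
    ks = list(ks)
    if not ks:
        raise ValueError("depth grid must be non-empty")
    if any(k < 1 for k in ks):
        raise ValueError("depths must be positive")
    if ks != sorted(ks):
        raise ValueError("depth grid must be ascending")

    rows: list[DepthProfileRow] = []
    n_universe = len(table.query_universe)
    for k in ks:
        t = truncate_depth(table, k)
        qa = collect_query_pmids(t, links)
        annotated = qa.annotated_queries
        pct = 100.0 * len(annotated) / n_universe if n_universe else 0.0

        identities = [h.percent_identity for h in t.iter_hits()]
        mean_ident = sum(identities) / len(identities) if identities else None

        per_query_counts = [len(qa.pmids[q]) for q in sorted(annotated)]
        apaq = (
            sum(per_query_counts) / len(per_query_counts)
            if per_query_counts else 0.0
        )

        pooled = qa.pooled_pmids()
        terms: set[str] = set()
        tokens = 0
        for pmid in pooled:
            rec = store.get(pmid)
            if rec is None:
                continue
            all_terms = rec.major_terms | rec.minor_terms
            terms |= all_terms
            tokens += len(all_terms)

        rows.append(
            DepthProfileRow(
                k=k,
                pct_annotated=pct,
                mean_identity_pct=mean_ident,
                articles_per_annotated_query=apaq,
                total_mesh_terms=len(terms),
                total_articles=len(pooled),
                mesh_term_tokens=tokens,
            )
        )
    return rows


def taxonomic_distribution(
    table: HitTable,
    acc2tax: Mapping[str, int],
    names: Mapping[int, str] | None = None,
) -> DistributionTable:
    """Count the best hit's taxon once per query with at least one hit.

    One vote per query (its rank-1 subject), so deep hit lists cannot swamp
    the table. Accessions without a taxid mapping are binned as "unknown".
    """
    names = names or {}
    counts: dict[str, int] = {}
    for query_id in sorted(table.hits):
        hit_list = table.hits[query_id]
        if not hit_list:
            continue
        best = hit_list[0]
        taxid = acc2tax.get(best.subject_accession)
        if taxid is None:
            label = "unknown"
        else:
            label = names.get(taxid, str(taxid))
        counts[label] = counts.get(label, 0) + 1
    return DistributionTable(counts=counts)


def journal_distribution(qa: QueryArticles, store: ArticleStore) -> DistributionTable:
    """Count journals over the distinct PMIDs pooled across all queries.

    An article cited by many queries counts once — the table describes the
    evidence corpus, not per-query citation intensity. PMIDs absent from the
    store are skipped.
    """
    counts: dict[str, int] = {}
    for pmid in qa.pooled_pmids():
        rec = store.get(pmid)
        if rec is None:
            continue
        counts[rec.journal] = counts.get(rec.journal, 0) + 1
    return DistributionTable(counts=counts)


def job_id(file_bytes: bytes) -> str:
    """MD5 of the uploaded bytes as 32 lowercase hex chars.

    Identical uploads map to identical job IDs, which is what lets repeat
    submissions be served from the existing result.
    """
    return hashlib.md5(file_bytes).hexdigest()


@dataclass
class AnnotationResult:
    """Everything an annotation run produces, ready for rendering."""

    config: AnnotationConfig
    top_major: list[TermSummary]
    top_minor: list[TermSummary]
    top_immune: list[TermSummary]
    major_summaries: list[TermSummary]
    minor_summaries: list[TermSummary]
    taxonomic: DistributionTable
    journals: DistributionTable
    depth_profile: list[DepthProfileRow]
    n_queries: int
    n_annotated: int

    def to_json_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "n_annotated": self.n_annotated,
            "top_major": term_summaries_to_json(self.top_major),
            "top_minor": term_summaries_to_json(self.top_minor),
            "top_immune": term_summaries_to_json(self.top_immune),
            "major_summaries": term_summaries_to_json(self.major_summaries),
            "minor_summaries": term_summaries_to_json(self.minor_summaries),
            "taxonomic_distribution": dict(self.taxonomic.items()),
            "journal_distribution": dict(self.journals.items()),
            "depth_profile": [
                {
                    "k": r.k,
                    "pct_annotated": r.pct_annotated,
                    "mean_identity_pct": r.mean_identity_pct,
                    "articles_per_annotated_query": r.articles_per_annotated_query,
                    "total_mesh_terms": r.total_mesh_terms,
                    "total_articles": r.total_articles,
                    "mesh_term_tokens": r.mesh_term_tokens,
                }
                for r in self.depth_profile
            ],
        }


def run_annotation(
    table: HitTable,
    links: LinkMap,
    store: ArticleStore,
    mesh_tree: MeshTreeMap,
    cfg: AnnotationConfig | None = None,
    acc2tax: Mapping[str, int] | None = None,
    tax_names: Mapping[int, str] | None = None,
    depth_grid: Sequence[int] | None = None,
    prefiltered: bool = False,
) -> AnnotationResult:
    """Run the full annotation pipeline on in-memory inputs.

    Filters the hit table (unless ``prefiltered``), collects per-query
    article sets, scores both facets, ranks and restricts terms, and builds
    the distribution tables; the depth scan runs only when ``depth_grid``
    is given (it multiplies the work by the grid length).
    """
    from .blast_io import apply_hit_filters

    cfg = cfg or AnnotationConfig()
    filtered = table if prefiltered else apply_hit_filters(table, cfg)
    qa = collect_query_pmids(filtered, links)

    per_query: dict[str, list[QueryTermScores]] = {"major": [], "minor": []}
    for query_id in sorted(qa.pmids):
        pmids = qa.pmids[query_id]
        if not pmids:
            continue
        for facet in ("major", "minor"):
            qts = score_query(pmids, store, facet, query_id=query_id)
            if qts.scores:
                per_query[facet].append(qts)

    major_summaries = aggregate_terms(per_query["major"])
    minor_summaries = aggregate_terms(per_query["minor"])
    immune = filter_categories(major_summaries, mesh_tree, cfg.immune_categories)

    return AnnotationResult(
        config=cfg,
        top_major=top_n(major_summaries, cfg.top_n_major),
        top_minor=top_n(minor_summaries, cfg.top_n_minor),
        top_immune=top_n(immune, cfg.top_n_immune),
        major_summaries=major_summaries,
        minor_summaries=minor_summaries,
        taxonomic=taxonomic_distribution(filtered, acc2tax or {}, tax_names),
        journals=journal_distribution(qa, store),
        depth_profile=(
            depth_scan(filtered, links, store, depth_grid) if depth_grid else []
        ),
        n_queries=len(filtered.query_universe),
        n_annotated=len(qa.annotated_queries),
    )


REPORT_FILES = (
    "top_major.tsv",
    "top_minor.tsv",
    "top_immune.tsv",
    "taxonomic_distribution.tsv",
    "journal_distribution.tsv",
    "depth_scan.tsv",
    "evidence.json",
)


def _write_distribution(dist: DistributionTable, stream: IO[str], label: str) -> None:
    stream.write(f"{label}\tcount\n")
    for name, count in dist.items():
        stream.write(f"{name}\t{count}\n")


def render_report(
    result: AnnotationResult, out_dir: str, formats: Sequence[str] = ("tsv", "json")
) -> list[str]:
    """Write the report file set; returns the paths written.

    TSV tables display scores to 2 decimals and percentages to 1; the JSON
    evidence bundle keeps full precision and the supporting query IDs.
    Deterministic for fixed inputs.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def _path(name: str) -> str:
        p = os.path.join(out_dir, name)
        written.append(p)
        return p

    if "tsv" in formats:
        with open(_path("top_major.tsv"), "w") as fh:
            write_term_summary_tsv(result.top_major, fh)
        with open(_path("top_minor.tsv"), "w") as fh:
            write_term_summary_tsv(result.top_minor, fh)
        with open(_path("top_immune.tsv"), "w") as fh:
            write_term_summary_tsv(result.top_immune, fh)
        with open(_path("taxonomic_distribution.tsv"), "w") as fh:
            _write_distribution(result.taxonomic, fh, "taxon")
        with open(_path("journal_distribution.tsv"), "w") as fh:
            _write_distribution(result.journals, fh, "journal")
        with open(_path("depth_scan.tsv"), "w") as fh:
            fh.write(
                "k\tpct_annotated\tmean_identity_pct\t"
                "articles_per_annotated_query\ttotal_mesh_terms\ttotal_articles\n"
            )
            for r in result.depth_profile:
                ident = "" if r.mean_identity_pct is None else f"{r.mean_identity_pct:.1f}"
                fh.write(
                    f"{r.k}\t{r.pct_annotated:.1f}\t{ident}\t"
                    f"{r.articles_per_annotated_query:.2f}\t"
                    f"{r.total_mesh_terms}\t{r.total_articles}\n"
                )
    if "json" in formats:
        with open(_path("evidence.json"), "w") as fh:
            json.dump(result.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
    return written


def load_report_json(path: str) -> dict:
    """Reload the JSON evidence bundle written by :func:`render_report`."""
    with open(path) as fh:
        return json.load(fh)
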
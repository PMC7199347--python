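"""Depth scans, distribution tables, job IDs and report rendering."""

import json
import os

import numpy as np
import pytest

from meshblast.blast_io import AnnotationConfig, apply_hit_filters, parse_hit_table
from meshblast.literature import QueryArticles, collect_query_pmids
from meshblast.mesh import ArticleRecord, ArticleStore
from meshblast.reports import (
    depth_scan,
    job_id,
    journal_distribution,
    load_report_json,
    render_report,
    run_annotation,
    taxonomic_distribution,
    REPORT_FILES,
)
from meshblast.synth import CorpusSpec, generate_corpus

from conftest import random_hit_table


def two_query_fixture():
    """Query A annotated via its rank-1 hit; query B only via its rank-10 hit."""
    lines = []
    for rank in range(1, 11):
        lines.append(
            f"qA\tAA_{rank}.1\t{95 - rank}\t100\t1\t1\t1\t300\t1\t100\t1e-20\t400"
        )
        lines.append(
            f"qB\tBB_{rank}.1\t{95 - rank}\t100\t1\t1\t1\t300\t1\t100\t1e-20\t400"
        )
    table = parse_hit_table("\n".join(lines) + "\n")
    links = {f"AA_{r}.1": set() for r in range(1, 11)}
    links.update({f"BB_{r}.1": set() for r in range(1, 11)})
    links["AA_1.1"] = {100}
    links["BB_10.1"] = {200}
    store = ArticleStore()
    store.add(ArticleRecord(100, "J One", 2010, frozenset({"T"}), frozenset()))
    store.add(ArticleRecord(200, "J Two", 2011, frozenset(), frozenset({"U"})))
    return apply_hit_filters(table, AnnotationConfig()), links, store


class TestDepthScan:
    def test_hand_enumerable_annotation_coverage(self):
        table, links, store = two_query_fixture()
        rows = depth_scan(table, links, store, ks=[1, 10])
        assert rows[0].pct_annotated == 50.0
        assert rows[1].pct_annotated == 100.0
        assert rows[0].total_articles == 1
        assert rows[1].total_articles == 2

    def test_depth_beyond_lists_equals_full_table_row(self):
        table, links, store = two_query_fixture()
        r10, r999 = depth_scan(table, links, store, ks=[10, 999])
        assert (r999.pct_annotated, r999.total_articles, r999.mean_identity_pct) == (
            r10.pct_annotated, r10.total_articles, r10.mean_identity_pct
        )

    def test_empty_or_unsorted_grid_rejected(self):
        table, links, store = two_query_fixture()
        with pytest.raises(ValueError):
            depth_scan(table, links, store, ks=[])
        with pytest.raises(ValueError):
            depth_scan(table, links, store, ks=[5, 1])

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_coverage_on_random_tables(self, seed):
        rng = np.random.default_rng(400 + seed)
        table = apply_hit_filters(random_hit_table(rng), AnnotationConfig())
        store = ArticleStore()
        for pmid in range(1, 40):
            store.add(ArticleRecord(pmid, "J", 2000,
                                    frozenset({f"T{pmid % 5}"}), frozenset()))
        links = {
            a: set(int(p) for p in rng.integers(1, 40, size=rng.integers(0, 3)))
            for a in table.accessions()
        }
        rows = depth_scan(table, links, store, ks=[1, 2, 4, 8, 16, 32])
        for prev, cur in zip(rows, rows[1:]):
            assert cur.pct_annotated >= prev.pct_annotated
            assert cur.total_articles >= prev.total_articles
            assert cur.total_mesh_terms >= prev.total_mesh_terms

    def test_mean_identity_non_increasing_on_decaying_fixture(self):
        bundle = generate_corpus(CorpusSpec(seed=5))
        table = apply_hit_filters(bundle.hit_table(), AnnotationConfig())
        rows = depth_scan(table, bundle.link_map(), bundle.article_store(),
                          ks=[1, 2, 3, 5, 8, 10])
        for prev, cur in zip(rows, rows[1:]):
            assert cur.mean_identity_pct <= prev.mean_identity_pct + 1e-9


class TestDistributions:
    def test_taxonomic_counts_best_hit_per_query(self):
        lines = [
            "q1\tA1.1\t90\t100\t1\t1\t1\t300\t1\t100\t1e-20\t400",
            "q1\tA2.1\t80\t100\t1\t1\t1\t300\t1\t100\t1e-20\t300",
            "q2\tA3.1\t90\t100\t1\t1\t1\t300\t1\t100\t1e-20\t400",
            "q3\tA4.1\t90\t100\t1\t1\t1\t300\t1\t100\t1e-20\t400",
            "q4\tA5.1\t90\t100\t1\t1\t1\t300\t1\t100\t1e-20\t400",
        ]
        table = parse_hit_table("\n".join(lines) + "\n",
                                query_universe={"q1", "q2", "q3", "q4", "q5"})
        acc2tax = {"A1.1": 8001, "A2.1": 8002, "A3.1": 8001, "A4.1": 8001}
        names = {8001: "fishA", 8002: "fishB"}
        dist = taxonomic_distribution(table, acc2tax, names)
        assert dist.counts == {"fishA": 3, "unknown": 1}
        # one vote per query with >=1 hit; hitless q5 contributes nothing
        assert dist.total() == 4

    def test_taxonomic_conservation_on_random_tables(self):
        rng = np.random.default_rng(17)
        table = apply_hit_filters(random_hit_table(rng), AnnotationConfig())
        acc2tax = {a: int(rng.integers(8001, 8006)) for a in table.accessions()}
        dist = taxonomic_distribution(table, acc2tax)
        assert dist.total() == sum(1 for q in table.hits if table.hits[q])

    def test_journal_counts_distinct_pooled_articles(self):
        store = ArticleStore()
        for pmid, journal in [(1, "J1"), (2, "J1"), (3, "J2")]:
            store.add(ArticleRecord(pmid, journal, 2000, frozenset(), frozenset()))
        qa = QueryArticles(pmids={"q1": frozenset({1, 2}),
                                  "q2": frozenset({2, 3})})
        dist = journal_distribution(qa, store)
        assert dist.counts == {"J1": 2, "J2": 1}
        assert dist.total() == len(qa.pooled_pmids())

    def test_empty_query_articles_gives_empty_table(self):
        assert journal_distribution(QueryArticles(pmids={}),
                                    ArticleStore()).counts == {}

    def test_ranking_by_count_then_label(self):
        store = ArticleStore()
        for pmid, journal in [(1, "B"), (2, "A"), (3, "A"), (4, "C")]:
            store.add(ArticleRecord(pmid, journal, 2000, frozenset(), frozenset()))
        qa = QueryArticles(pmids={"q": frozenset({1, 2, 3, 4})})
        assert journal_distribution(qa, store).items() == [
            ("A", 2), ("B", 1), ("C", 1)
        ]


class TestJobId:
    def test_rfc1321_vectors(self):
        assert job_id(b"") == "d41d8cd98f00b204e9800998ecf8427e"
        assert job_id(b"abc") == "900150983cd24fb0d6963f7d28e17f72"

    def test_identical_bytes_identical_ids(self):
        data = b">contig_1\nACGTACGT\n"
        assert job_id(data) == job_id(bytes(data))


class TestRenderReport:
    def test_file_set_and_json_round_trip(self, tmp_path):
        bundle = generate_corpus(CorpusSpec(seed=3))
        result = run_annotation(
            bundle.hit_table(), bundle.link_map(), bundle.article_store(),
            bundle.mesh_tree(), acc2tax=bundle.acc2tax(),
            tax_names=bundle.tax_names(), depth_grid=(1, 5, 10),
        )
        out_dir = str(tmp_path / "report")
        written = render_report(result, out_dir)
        assert sorted(os.path.basename(p) for p in written) == sorted(REPORT_FILES)
        reloaded = load_report_json(os.path.join(out_dir, "evidence.json"))
        assert reloaded == json.loads(json.dumps(result.to_json_dict()))

    def test_tsv_score_formatting_two_decimals(self, tmp_path):
        bundle = generate_corpus(CorpusSpec(seed=3))
        result = run_annotation(
            bundle.hit_table(), bundle.link_map(), bundle.article_store(),
            bundle.mesh_tree(),
        )
        render_report(result, str(tmp_path))
        with open(tmp_path / "top_major.tsv") as fh:
            header = fh.readline()
            first = fh.readline().rstrip("\n").split("\t")
        assert header == "term\tscore\tannotated_queries\n"
        whole, _, frac = first[1].partition(".")
        assert len(frac) == 2  # "16.80"-style display

    def test_deterministic_for_fixed_inputs(self, tmp_path):
        bundle = generate_corpus(CorpusSpec(seed=4))
        kwargs = dict(
            links=bundle.link_map(), store=bundle.article_store(),
            mesh_tree=bundle.mesh_tree(),
        )
        r1 = run_annotation(bundle.hit_table(), **kwargs)
        r2 = run_annotation(bundle.hit_table(), **kwargs)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        render_report(r1, str(d1))
        render_report(r2, str(d2))
        for name in REPORT_FILES:
            assert (d1 / name).read_text() == (d2 / name).read_text()
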
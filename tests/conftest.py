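"""Shared fixtures: tiny hand-checkable inputs and random-table helpers."""

from __future__ import annotations

import numpy as np
import pytest

from meshblast.blast_io import HitTable, parse_hit_table

# --- tiny hand-written hit table ---------------------------------------

HIT_ROWS = [
    # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore
    "q1\tXP_1.1\t93.5\t200\t10\t2\t1\t600\t1\t200\t1e-50\t200",
    "q1\tXP_2.1\t85.0\t180\t20\t1\t1\t540\t1\t180\t1e-40\t150",
    "q1\tXP_1.1\t80.0\t150\t25\t3\t1\t450\t1\t150\t1e-30\t120",  # dup subject
    "q1\tXP_3.1\t39.9\t100\t40\t5\t1\t300\t1\t100\t1e-20\t90",   # below floor
    "q1\tXP_4.1\t55.0\t100\t30\t4\t1\t300\t1\t100\t1e-5\t60",    # above cutoff
    "q2\tXP_5.1\t40.0\t120\t35\t2\t1\t360\t1\t120\t1e-06\t80",   # both boundaries
]


@pytest.fixture
def small_hit_table() -> HitTable:
    return parse_hit_table("\n".join(HIT_ROWS) + "\n",
                           query_universe={"q1", "q2", "q3"})


# --- random hit tables for filter/truncation properties ------------------

def random_hit_table(rng: np.random.Generator,
                     n_queries: int = 8,
                     max_hits: int = 40) -> HitTable:
    """Random table with duplicate subjects and out-of-band identities/E-values."""
    lines = []
    for qi in range(n_queries):
        n = int(rng.integers(0, max_hits + 1))
        for _ in range(n):
            acc = f"ACC_{int(rng.integers(0, 25)):03d}.1"
            pident = float(rng.uniform(20.0, 100.0))
            evalue = 10.0 ** float(rng.uniform(-30.0, -3.0))
            lines.append(
                f"q{qi}\t{acc}\t{pident:.3f}\t100\t5\t1\t1\t300\t1\t100\t"
                f"{evalue:.4g}\t{float(rng.uniform(50, 500)):.1f}"
            )
    return parse_hit_table("\n".join(lines) + ("\n" if lines else ""),
                           query_universe={f"q{i}" for i in range(n_queries)})


# --- MEDLINE XML builder --------------------------------------------------

def medline_xml(records: list[dict]) -> str:
    """Build MEDLINE/PubMed citation XML from record dicts.

    Keys: pmid (None to omit the element), journal, year or medline_date,
    headings = list of (descriptor, descriptor_major, [(qualifier, major)...]).
    """
    parts = ['<?xml version="1.0"?>', "<PubmedArticleSet>"]
    for rec in records:
        parts.append("<PubmedArticle><MedlineCitation>")
        if rec.get("pmid") is not None:
            parts.append(f"<PMID Version=\"1\">{rec['pmid']}</PMID>")
        parts.append("<Article><Journal>")
        parts.append(f"<Title>{rec.get('journal', '')}</Title>")
        parts.append("<JournalIssue><PubDate>")
        if "year" in rec:
            parts.append(f"<Year>{rec['year']}</Year>")
        elif "medline_date" in rec:
            parts.append(f"<MedlineDate>{rec['medline_date']}</MedlineDate>")
        parts.append("</PubDate></JournalIssue></Journal></Article>")
        headings = rec.get("headings", [])
        if headings:
            parts.append("<MeshHeadingList>")
            for descriptor, major, qualifiers in headings:
                parts.append("<MeshHeading>")
                yn = "Y" if major else "N"
                parts.append(
                    f'<DescriptorName MajorTopicYN="{yn}">{descriptor}</DescriptorName>'
                )
                for qname, qmajor in qualifiers:
                    qyn = "Y" if qmajor else "N"
                    parts.append(
                        f'<QualifierName MajorTopicYN="{qyn}">{qname}</QualifierName>'
                    )
                parts.append("</MeshHeading>")
            parts.append("</MeshHeadingList>")
        parts.append("</MedlineCitation></PubmedArticle>")
    parts.append("</PubmedArticleSet>")
    return "\n".join(parts)


@pytest.fixture
def medline_fixture_records() -> list[dict]:
    """Ten records exercising the major/minor partition and year fallbacks."""
    return [
        {"pmid": 100 + i, "journal": f"J Fix {i % 3}", "year": 2010 + i,
         "headings": [
             ("Signal Transduction", i % 2 == 0, []),
             ("Brain", False, [("metabolism", False)]),
             ("Liver", False, [("immunology", i % 3 == 0)]),
             ("Apoptosis", True, []) if i % 4 == 0 else ("Spleen", False, []),
         ]}
        for i in range(9)
    ] + [
        {"pmid": 200, "journal": "J Range", "medline_date": "1998 Dec-1999 Jan",
         "headings": []},
    ]
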
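"""Article metadata store and the MeSH descriptor tree map.

Each PubMed article carries journal, publication year and its MeSH headings
partitioned into *major* terms (flagged as a central topic by NLM indexers,
on the descriptor or any of its qualifiers) and *minor* terms (the rest).
The tree map places descriptors in the MeSH hierarchy by dot-separated tree
numbers; the annotation pipeline uses it only to restrict term tables to
whole categories (by default A15, Hemic and Immune Systems, and G12, Immune
System Phenomena).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import ParseError

__all__ = [
    "ArticleRecord",
    "ArticleStore",
    "MeshTreeMap",
    "parse_medline_xml",
    "load_article_tsv",
    "dump_article_tsv",
    "load_mesh_tree",
    "term_in_categories",
]

logger = logging.getLogger(__name__)

#: descriptor name → set of tree numbers (e.g. "A15.382.490").
MeshTreeMap = dict[str, set[str]]

_YEAR_RE = re.compile(r"\b(\d{4})\b")


@dataclass(frozen=True)
class ArticleRecord:
    """One article's metadata: journal, year, and partitioned MeSH headings.

    ``year`` is 0 when no 4-digit year could be recovered from the record.
    """

    pmid: int
    journal: str
    year: int
    major_terms: frozenset[str]
    minor_terms: frozenset[str]

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError(f"PMID must be positive, got {self.pmid}")
        overlap = self.major_terms & self.minor_terms
        if overlap:
            raise ValueError(
                f"PMID {self.pmid}: terms in both major and minor sets: "
                f"{sorted(overlap)[:3]}"
            )

    def terms(self, facet: str) -> frozenset[str]:
        if facet == "major":
            return self.major_terms
        if facet == "minor":
            return self.minor_terms
        raise ValueError(f"facet must be 'major' or 'minor', got {facet!r}")


@dataclass
class ArticleStore:
    """PMID-keyed article metadata with provenance.

    A PMID absent from the store is distinguishable (``get`` returns None)
    from a present article that simply has no MeSH headings.
    """

    records: dict[int, ArticleRecord] = field(default_factory=dict)
    provenance: str = ""

    def get(self, pmid: int) -> ArticleRecord | None:
        return self.records.get(pmid)

    def __contains__(self, pmid: int) -> bool:
        return pmid in self.records

    def __len__(self) -> int:
        return len(self.records)

    def add(self, record: ArticleRecord) -> None:
        if record.pmid in self.records:
            raise ValueError(f"duplicate PMID {record.pmid}")
        self.records[record.pmid] = record


def _extract_year(citation) -> int:
    # Prefer PubDate/Year; fall back to the first 4-digit run in MedlineDate
    # (range-style dates like "1998 Dec-1999 Jan"); else the 0 sentinel.
    year_el = citation.find(".//Journal/JournalIssue/PubDate/Year")
    if year_el is not None and year_el.text and year_el.text.strip().isdigit():
        return int(year_el.text.strip())
    mdate = citation.find(".//Journal/JournalIssue/PubDate/MedlineDate")
    if mdate is not None and mdate.text:
        m = _YEAR_RE.search(mdate.text)
        if m:
            return int(m.group(1))
    return 0


def parse_medline_xml(
    source: IO[bytes] | IO[str] | str | bytes, strict: bool = False
) -> list[ArticleRecord]:
    """Parse MEDLINE/PubMed citation XML into article records.

    A heading's descriptor lands in ``major_terms`` iff the descriptor itself
    or any attached qualifier carries ``MajorTopicYN="Y"``; otherwise it is a
    minor term. Qualifier names are never emitted as terms.

    Records without a PMID are skipped with a warning (or abort the parse
    when ``strict=True``). Malformed XML raises :class:`ParseError`.
    """
    from lxml import etree

    if isinstance(source, str):
        source = source.encode()
    if isinstance(source, bytes):
        source = io.BytesIO(source)
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed MEDLINE XML: {exc}") from exc

    records: list[ArticleRecord] = []
    skipped = 0
    for citation in tree.iter("MedlineCitation"):
        pmid_el = citation.find("PMID")
        if pmid_el is None or not (pmid_el.text or "").strip().isdigit():
            skipped += 1
            if strict:
                raise ParseError("MedlineCitation without a numeric PMID")
            continue
        pmid = int(pmid_el.text.strip())
        journal_el = citation.find(".//Journal/Title")
        journal = (journal_el.text or "").strip() if journal_el is not None else ""
        year = _extract_year(citation)

        major: set[str] = set()
        minor: set[str] = set()
        for heading in citation.findall(".//MeshHeadingList/MeshHeading"):
            desc = heading.find("DescriptorName")
            if desc is None or not (desc.text or "").strip():
                continue
            name = desc.text.strip()
            is_major = desc.get("MajorTopicYN") == "Y" or any(
                q.get("MajorTopicYN") == "Y"
                for q in heading.findall("QualifierName")
            )
            (major if is_major else minor).add(name)
        # A descriptor repeated with different qualifier flags: major wins.
        minor -= major
        records.append(
            ArticleRecord(
                pmid=pmid,
                journal=journal,
                year=year,
                major_terms=frozenset(major),
                minor_terms=frozenset(minor),
            )
        )
    if skipped:
        logger.warning("skipped %d MEDLINE records without a PMID", skipped)
    return records


_TSV_HEADER = "pmid\tjournal\tyear\tmajor\tminor"


def dump_article_tsv(store: ArticleStore, stream: IO[str]) -> None:
    """Write the fixture-scale TSV dialect: pmid, journal, year, major, minor.

    Term sets are semicolon-joined in sorted order. Lossless round-trip with
    :func:`load_article_tsv` for term names free of tabs and semicolons.
    """
    stream.write(_TSV_HEADER + "\n")
    for pmid in sorted(store.records):
        rec = store.records[pmid]
        stream.write(
            f"{rec.pmid}\t{rec.journal}\t{rec.year}\t"
            f"{';'.join(sorted(rec.major_terms))}\t"
            f"{';'.join(sorted(rec.minor_terms))}\n"
        )


def load_article_tsv(
    stream: IO[str] | str | Iterable[str], provenance: str = ""
) -> ArticleStore:
    """Load the article TSV dialect written by :func:`dump_article_tsv`."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    store = ArticleStore(provenance=provenance)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#") or line == _TSV_HEADER:
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(
                f"expected 5 tab-separated columns, got {len(fields)}", line=lineno
            )
        pmid_text, journal, year_text, major_text, minor_text = fields
        try:
            pmid = int(pmid_text)
            year = int(year_text)
        except ValueError as exc:
            raise ParseError(f"non-integer pmid/year: {exc}", line=lineno) from exc
        major = frozenset(t for t in major_text.split(";") if t)
        minor = frozenset(t for t in minor_text.split(";") if t)
        try:
            record = ArticleRecord(
                pmid=pmid, journal=journal, year=year,
                major_terms=major, minor_terms=minor,
            )
            store.add(record)
        except ValueError as exc:
            raise ParseError(str(exc), line=lineno) from exc
    return store


def load_mesh_tree(stream: IO[str] | str | Iterable[str]) -> MeshTreeMap:
    """Load a ``descriptor<TAB>tree_number`` TSV; repeated descriptors merge.

    Descriptors absent from the file are simply unmapped (category unknown);
    an empty tree-number field is a parse error.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    tree: MeshTreeMap = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"expected 2 tab-separated columns, got {len(fields)}", line=lineno
            )
        descriptor, tree_number = fields[0].strip(), fields[1].strip()
        if not tree_number:
            raise ParseError("empty tree-number field", line=lineno)
        tree.setdefault(descriptor, set()).add(tree_number)
    return tree


def term_in_categories(
    term: str, tree: MeshTreeMap, categories: Iterable[str]
) -> bool:
    """True iff the term has a tree number inside any of the given categories.

    Matching is dot-boundary aware: prefix "A15" matches tree numbers "A15"
    and "A15.x.y" but never "A150.x". Unmapped terms are never in a category.
    """
    tree_numbers = tree.get(term)
    if not tree_numbers:
        return False
    for cat in categories:
        for tn in tree_numbers:
            if tn == cat or tn.startswith(cat + "."):
                return True
    return False
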
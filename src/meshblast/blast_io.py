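"""Reading, filtering and depth-truncation of BLAST tabular hit tables.

The hit table is the entry point of the annotation pipeline: each de novo
contig (query) carries an ordered list of protein hits, trusted in the order
BLAST emitted them (descending bitscore). Filtering drops low-identity and
non-significant alignments, deduplicates subject accessions per query, and
caps the list at the configured hit depth; depth truncation then models the
effect of BLAST's ``max_target_seqs`` without re-running BLAST.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator

from .errors import ParseError

__all__ = [
    "BlastHit",
    "HitTable",
    "AnnotationConfig",
    "parse_hit_table",
    "apply_hit_filters",
    "truncate_depth",
    "build_blastx_invocation",
    "write_hit_table",
    "read_fasta_ids",
]

#: Column order of BLAST ``-outfmt 6`` (and the tabular body of ``-outfmt 7``).
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class BlastHit:
    """One alignment record from a tabular BLAST report.

    ``rank`` is the 1-based position of the hit within its query's hit list;
    after filtering, survivors are re-ranked to stay consecutive from 1.
    """

    query_id: str
    subject_accession: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    rank: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")
        if self.rank < 1:
            raise ValueError(f"rank {self.rank} < 1")

    def to_row(self) -> str:
        """Serialize back to one outfmt-6 line (without trailing newline)."""
        return "\t".join(
            (
                self.query_id,
                self.subject_accession,
                format_pident(self.percent_identity),
                str(self.align_length),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                format_evalue(self.evalue),
                format_bitscore(self.bitscore),
            )
        )


def format_pident(x: float) -> str:
    s = f"{x:.3f}".rstrip("0").rstrip(".")
    return s if s else "0"


def format_evalue(x: float) -> str:
    if x == 0.0:
        return "0.0"
    return f"{x:.6g}"


def format_bitscore(x: float) -> str:
    return f"{x:.6g}"


@dataclass
class HitTable:
    """Hits grouped by query, plus the universe of submitted query IDs.

    ``query_universe`` may be wider than the keys of ``hits``: queries present
    in the submitted FASTA but absent from the BLAST output (zero hits) still
    count in annotation-percentage denominators.
    """

    hits: dict[str, list[BlastHit]]
    query_universe: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set(self.hits) - set(self.query_universe)
        if missing:
            raise ValueError(
                f"hits reference queries outside query_universe: {sorted(missing)[:5]}"
            )

    def hits_for(self, query_id: str) -> list[BlastHit]:
        return self.hits.get(query_id, [])

    def iter_hits(self) -> Iterator[BlastHit]:
        for hit_list in self.hits.values():
            yield from hit_list

    @property
    def n_hits(self) -> int:
        return sum(len(v) for v in self.hits.values())

    def accessions(self) -> list[str]:
        """Distinct subject accessions, in first-encounter order."""
        seen: dict[str, None] = {}
        for hit in self.iter_hits():
            seen.setdefault(hit.subject_accession, None)
        return list(seen)


@dataclass(frozen=True)
class AnnotationConfig:
    """Filtering and report-size parameters of the annotation pipeline.

    Defaults are the published operating point of the method: E-value cutoff
    1e-6, identity floor 40%, up to 500 hits per query, immune restriction to
    MeSH categories A15 (Hemic and Immune Systems) and G12 (Immune System
    Phenomena), and top-20/top-10/top-10 report lengths for major, minor and
    immune-specific term tables.
    """

    evalue_cutoff: float = 1e-6
    identity_floor_pct: float = 40.0
    max_hits_per_query: int = 500
    immune_categories: frozenset[str] = frozenset({"A15", "G12"})
    top_n_major: int = 20
    top_n_minor: int = 10
    top_n_immune: int = 10

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if not 0.0 <= self.identity_floor_pct <= 100.0:
            raise ValueError("identity_floor_pct must be in [0, 100]")
        if self.max_hits_per_query < 1:
            raise ValueError("max_hits_per_query must be >= 1")


def _as_lines(stream: IO[str] | str | Iterable[str]) -> Iterable[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_hit_table(
    stream: IO[str] | str | Iterable[str],
    query_universe: Iterable[str] | None = None,
    provenance: str = "",
) -> HitTable:
    """Parse a 12-column BLAST tabular report (outfmt 6, or 7 with ``#`` comments).

    Hits are grouped by query in file order and ranked by encounter order
    within each query. When ``query_universe`` is not supplied it defaults to
    the queries seen in the file. An empty stream yields an empty table.

    Raises
    ------
    ParseError
        On a row with the wrong column count or a non-numeric numeric field,
        naming the offending 1-based line number.
    """
    hits: dict[str, list[BlastHit]] = {}
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(OUTFMT6_COLUMNS):
            raise ParseError(
                f"expected {len(OUTFMT6_COLUMNS)} tab-separated columns, "
                f"got {len(fields)}",
                line=lineno,
            )
        try:
            hit = BlastHit(
                query_id=fields[0],
                subject_accession=fields[1],
                percent_identity=float(fields[2]),
                align_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
                rank=len(hits.get(fields[0], ())) + 1,
            )
        except ValueError as exc:
            raise ParseError(f"malformed hit row: {exc}", line=lineno) from exc
        hits.setdefault(hit.query_id, []).append(hit)

    if query_universe is None:
        universe = frozenset(hits)
    else:
        universe = frozenset(query_universe) | frozenset(hits)
    return HitTable(hits=hits, query_universe=universe, provenance=provenance)


def apply_hit_filters(table: HitTable, cfg: AnnotationConfig) -> HitTable:
    """Filter a hit table to the annotation operating point.

    Per query: drop hits below the identity floor (strictly lower than 40%
    by default — exactly 40.0 is kept) or above the E-value cutoff (exactly
    at the cutoff is kept, matching BLAST ``-evalue`` semantics), deduplicate
    subject accessions keeping the first (best-ranked) occurrence, truncate
    to the hit cap, and re-rank survivors 1..n. Queries whose every hit is
    filtered stay in the universe with an empty list. Idempotent.
    """
    out: dict[str, list[BlastHit]] = {}
    for query_id, hit_list in table.hits.items():
        kept: list[BlastHit] = []
        seen_subjects: set[str] = set()
        for hit in hit_list:
            if hit.percent_identity < cfg.identity_floor_pct:
                continue
            if hit.evalue > cfg.evalue_cutoff:
                continue
            if hit.subject_accession in seen_subjects:
                continue
            seen_subjects.add(hit.subject_accession)
            kept.append(replace(hit, rank=len(kept) + 1))
            if len(kept) >= cfg.max_hits_per_query:
                break
        out[query_id] = kept
    return HitTable(
        hits=out, query_universe=table.query_universe, provenance=table.provenance
    )


def truncate_depth(table: HitTable, k: int) -> HitTable:
    """Keep only hits with rank <= k per query (the ``max_target_seqs`` model).

    Nested by construction: the depth-k table is the depth-k' table restricted
    to rank <= k for any k <= k'.
    """
    if k < 1:
        raise ValueError(f"depth k must be >= 1, got {k}")
    out = {q: [h for h in hl if h.rank <= k] for q, hl in table.hits.items()}
    return HitTable(
        hits=out, query_universe=table.query_universe, provenance=table.provenance
    )


def build_blastx_invocation(
    query_fasta_path: str, db_path: str, cfg: AnnotationConfig
) -> list[str]:
    """Argument vector for the external six-frame translated search.

    Uses the fast translated-search task, the configured E-value cutoff and
    hit cap, and tabular output. Builds the command only; never executes it.
    """
    if not query_fasta_path or not db_path:
        raise ValueError("query FASTA path and database path must be non-empty")
    return [
        "blastx",
        "-task", "blastx-fast",
        "-query", query_fasta_path,
        "-db", db_path,
        "-evalue", format_evalue(cfg.evalue_cutoff),
        "-max_target_seqs", str(cfg.max_hits_per_query),
        "-outfmt", "6",
    ]


def write_hit_table(table: HitTable, stream: IO[str]) -> None:
    """Serialize in the same outfmt-6 dialect the parser reads (round-trippable)."""
    for hit in table.iter_hits():
        stream.write(hit.to_row())
        stream.write("\n")


def read_fasta_ids(source: IO[str] | str) -> frozenset[str]:
    """Extract the query universe (sequence IDs) from a FASTA file or handle."""
    from Bio import SeqIO

    if isinstance(source, str):
        with open(source) as fh:
            return frozenset(rec.id for rec in SeqIO.parse(fh, "fasta"))
    return frozenset(rec.id for rec in SeqIO.parse(source, "fasta"))
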
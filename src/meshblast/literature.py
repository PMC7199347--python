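"""Resolving protein accessions to PubMed article IDs.

Two interchangeable backends produce the same accession→PMID map: a plain
two-column TSV (the offline path used in tests and batch runs) and an
Entrez ELink client (protein → pubmed cross-links) hidden behind a minimal
request contract so the pipeline itself never touches the network. Each
query's article set is then the deduplicated union over its retained hit
accessions.
"""

from __future__ import annotations

import io
import logging
import time
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Protocol, Sequence

from .blast_io import HitTable
from .errors import LinkResolutionError, ParseError

__all__ = [
    "LinkMap",
    "QueryArticles",
    "LinkClient",
    "TransientLinkFailure",
    "load_link_table",
    "dump_link_table",
    "elink_resolve",
    "collect_query_pmids",
]

logger = logging.getLogger(__name__)

#: accession → set of PMIDs (possibly empty).
LinkMap = dict[str, set[int]]


@dataclass
class QueryArticles:
    """Per-query deduplicated PMID sets over a hit table's query universe.

    A query is *annotated* when its PMID set is non-empty.
    """

    pmids: dict[str, frozenset[int]]

    def is_annotated(self, query_id: str) -> bool:
        return bool(self.pmids.get(query_id))

    @property
    def annotated_queries(self) -> set[str]:
        return {q for q, s in self.pmids.items() if s}

    def pooled_pmids(self) -> frozenset[int]:
        """Distinct PMIDs pooled over all queries."""
        out: set[int] = set()
        for s in self.pmids.values():
            out |= s
        return frozenset(out)


def load_link_table(stream: IO[str] | str | Iterable[str]) -> LinkMap:
    """Load an ``accession<TAB>pmid`` TSV; repeated accessions merge.

    A row ``accession<TAB>-`` records an accession explicitly known to have
    no links (it appears in the map with an empty set).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    links: LinkMap = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"expected 2 tab-separated columns, got {len(fields)}", line=lineno
            )
        accession, pmid_text = fields
        bucket = links.setdefault(accession, set())
        if pmid_text == "-":
            continue
        try:
            pmid = int(pmid_text)
        except ValueError as exc:
            raise ParseError(f"non-integer PMID {pmid_text!r}", line=lineno) from exc
        if pmid <= 0:
            raise ParseError(f"PMID must be positive, got {pmid}", line=lineno)
        bucket.add(pmid)
    return links


def dump_link_table(links: LinkMap, stream: IO[str]) -> None:
    """Write a link map back to the two-column TSV dialect (sorted, lossless)."""
    for accession in sorted(links):
        pmids = links[accession]
        if not pmids:
            stream.write(f"{accession}\t-\n")
        for pmid in sorted(pmids):
            stream.write(f"{accession}\t{pmid}\n")


class TransientLinkFailure(Exception):
    """A retryable backend failure (timeout, throttling, 5xx)."""


class LinkClient(Protocol):
    """Contract a link backend must implement."""

    def request(self, accessions: Sequence[str]) -> Mapping[str, Iterable[int]]:
        """Return PMID lists for a batch; may omit link-free accessions."""
        ...


def elink_resolve(
    accessions: Iterable[str],
    client: LinkClient,
    batch_size: int = 200,
    max_retries: int = 3,
) -> LinkMap:
    """Resolve accessions through a link backend with batching and retry.

    Input accessions are deduplicated (first-seen order preserved) before any
    request. The result covers every requested accession — accessions the
    backend omits get an empty set. A batch that keeps failing after
    ``max_retries`` retries raises :class:`LinkResolutionError` naming the
    batch; accessions are never silently dropped.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    ordered: list[str] = list(dict.fromkeys(accessions))
    links: LinkMap = {}
    for start in range(0, len(ordered), batch_size):
        batch = ordered[start : start + batch_size]
        attempt = 0
        while True:
            try:
                response = client.request(batch)
                break
            except TransientLinkFailure as exc:
                attempt += 1
                if attempt > max_retries:
                    raise LinkResolutionError(
                        f"link backend failed {attempt} times for batch of "
                        f"{len(batch)} accessions starting at {batch[0]!r}: {exc}",
                        batch=tuple(batch),
                    ) from exc
                logger.warning(
                    "transient link failure (attempt %d/%d): %s",
                    attempt, max_retries, exc,
                )
        for accession in batch:
            links[accession] = set(int(p) for p in response.get(accession, ()))
    return links


class EntrezLinkClient:
    """Live NCBI ELink backend (``dbfrom=protein``, ``db=pubmed``).

    Paced at or below 3 requests/second per NCBI usage policy. Never used by
    the test suite; provided for real annotation runs with network access.
    """

    def __init__(self, email: str, api_key: str | None = None,
                 min_interval_s: float = 1.0 / 3.0):
        self.email = email
        self.api_key = api_key
        self.min_interval_s = min_interval_s
        self._last_request = 0.0

    def request(self, accessions: Sequence[str]) -> dict[str, list[int]]:
        from Bio import Entrez  # deferred: network path only

        Entrez.email = self.email
        if self.api_key:
            Entrez.api_key = self.api_key
        wait = self.min_interval_s - (time.monotonic() - self._last_request)
        if wait > 0:
            time.sleep(wait)
        self._last_request = time.monotonic()
        try:
            handle = Entrez.elink(
                dbfrom="protein", db="pubmed", id=list(accessions), idtype="acc"
            )
            parsed = Entrez.read(handle)
        except OSError as exc:
            raise TransientLinkFailure(str(exc)) from exc
        out: dict[str, list[int]] = {}
        for linkset in parsed:
            ids = linkset.get("IdList", [])
            key = str(ids[0]) if ids else ""
            pmids: list[int] = []
            for db in linkset.get("LinkSetDb", []):
                pmids.extend(int(link["Id"]) for link in db.get("Link", []))
            if key:
                out[key] = pmids
        return out


def collect_query_pmids(table: HitTable, links: LinkMap) -> QueryArticles:
    """Union each query's PMIDs over its retained subject accessions.

    Every query in the table's universe appears in the result; queries with
    no hits or no linked articles get an empty (unannotated) set. Accessions
    missing from the link map count as link-free — a warning, never an error,
    because real ELink coverage is spotty.
    """
    pmids: dict[str, frozenset[int]] = {}
    missing: set[str] = set()
    for query_id in sorted(table.query_universe):
        acc: set[int] = set()
        for hit in table.hits_for(query_id):
            if hit.subject_accession in links:
                acc |= links[hit.subject_accession]
            else:
                missing.add(hit.subject_accession)
        pmids[query_id] = frozenset(acc)
    if missing:
        logger.warning(
            "%d subject accessions absent from link map (treated as link-free)",
            len(missing),
        )
    return QueryArticles(pmids=pmids)
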
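"""Seeded synthetic corpora: a joint stand-in for BLAST output, protein→PubMed
links, and article metadata, with an optional planted enriched term.

The generator writes every file the annotation pipeline consumes — hit
table, link TSV, article TSV, MeSH tree TSV, accession→taxid TSV — as
mutually consistent text, so the full offline pipeline runs end to end with
no network and no downloads. A *planted* term appears at an elevated
per-article probability in the article pools of a chosen target-query
subset and at a low background probability elsewhere, giving every run a
known ground truth for enrichment-recovery checks.

It also hosts :func:`oracle_scores`, a deliberately naive triple-loop
reference computation of the correlation scores that shares no code with
the scoring module and exists purely to cross-check it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
import numpy as np

from .blast_io import HitTable, parse_hit_table
from .literature import LinkMap, load_link_table
from .mesh import ArticleStore, MeshTreeMap, load_article_tsv, load_mesh_tree

__all__ = [
    "VocabTerm",
    "PlantedSpec",
    "CorpusSpec",
    "CorpusBundle",
    "DEFAULT_VOCABULARY",
    "generate_corpus",
    "oracle_scores",
]

RNG_ALGORITHM = "numpy.default_rng (PCG64)"


@dataclass(frozen=True)
class VocabTerm:
    """One background vocabulary term.

    ``occurrence_prob`` is the per-article probability the term is assigned;
    ``major_prob`` the probability an occurrence is flagged as a major topic;
    ``tree_numbers`` its MeSH tree placements (empty = unmapped).
    """

    name: str
    occurrence_prob: float
    major_prob: float
    tree_numbers: tuple[str, ...] = ()


# A mix of immune-category (A15/G12), other-category, and unmapped terms so
# the category filter always has both outcomes to exercise. Occurrence
# probabilities span 0.02-0.20.
DEFAULT_VOCABULARY: tuple[VocabTerm, ...] = tuple(
    VocabTerm(name, occ, mp, tns)
    for name, occ, mp, tns in [
        ("Signal Transduction", 0.20, 0.5, ("G07.690",)),
        ("Fish Diseases", 0.18, 0.3, ("C22.362",)),
        ("Apoptosis", 0.15, 0.5, ("G04.299",)),
        ("Immunity, Innate", 0.12, 0.6, ("G12.450",)),
        ("Spleen", 0.10, 0.4, ("A15.382", "A10.549")),
        ("Brain", 0.16, 0.3, ("A08.186",)),
        ("Liver", 0.14, 0.3, ("A03.620",)),
        ("Host-Pathogen Interactions", 0.08, 0.5, ("G12.290",)),
        ("Cell Differentiation", 0.13, 0.4, ("G04.260",)),
        ("Transcription Factors", 0.17, 0.3, ("D12.776",)),
        ("Adaptive Immunity", 0.07, 0.6, ("G12.050",)),
        ("Macrophages", 0.09, 0.4, ("A15.145",)),
        ("Lymphocytes", 0.08, 0.4, ("A15.511",)),
        ("Cell Movement", 0.11, 0.4, ("G04.335",)),
        ("Genome, Viral", 0.05, 0.5, ("G05.360",)),
        ("Gene Regulatory Networks", 0.06, 0.4, ("G05.308",)),
        ("Wound Healing", 0.05, 0.4, ("G16.762",)),
        ("DNA Methylation", 0.04, 0.5, ("G05.219",)),
        ("Embryonic Development", 0.07, 0.4, ("G07.345",)),
        ("Disease Resistance", 0.03, 0.6, ("G12.250",)),
        ("Nerve Tissue Proteins", 0.12, 0.3, ("D12.644",)),
        ("Carrier Proteins", 0.10, 0.3, ("D12.776.157",)),
        ("Oncorhynchus mykiss", 0.06, 0.2, ("B01.050",)),
        ("Flatfishes", 0.04, 0.2, ("B01.050.150",)),
        ("Body Patterning", 0.05, 0.4, ("G07.345.249",)),
        ("Aquaculture Stress Response", 0.04, 0.4, ()),
        ("Mucosal Barrier Function", 0.03, 0.4, ()),
        ("Hepatic Lipid Storage", 0.05, 0.3, ()),
        ("Gill Ion Transport", 0.04, 0.3, ()),
        ("Larval Metamorphosis", 0.02, 0.4, ()),
    ]
)


@dataclass(frozen=True)
class PlantedSpec:
    """The planted enriched term and its ground-truth parameters.

    The term occurs with per-article probability ``p_hi`` in articles
    belonging to target queries and ``p_lo`` elsewhere; occurrences land in
    ``facet`` with probability ``facet_prob`` (else the other facet).
    """

    term: str = "Planted Immune Signature"
    n_target_queries: int = 20
    p_hi: float = 0.8
    p_lo: float = 0.05
    facet: str = "major"
    facet_prob: float = 1.0
    tree_numbers: tuple[str, ...] = ("A15.900",)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_lo < self.p_hi <= 1.0):
            raise ValueError("planted probabilities need 0 <= p_lo < p_hi <= 1")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic corpus.

    Defaults describe a mid-sized offline study: 50 queries, 10 retained
    hits each with identities decaying from 95% to 55% over the ranks, 250
    articles (an expected pool of 5 per query), about one PubMed link per
    accession, and a planted enriched major-facet term in 20 target queries
    (p_hi 0.8 vs background p_lo 0.05).
    """

    n_queries: int = 50
    hits_per_query: int = 10
    identity_decay: tuple[float, float] = (95.0, 55.0)
    identity_jitter: float = 0.0
    n_articles: int = 250
    vocabulary: tuple[VocabTerm, ...] = DEFAULT_VOCABULARY
    planted: PlantedSpec | None = PlantedSpec()
    link_density: float = 1.0
    accession_share_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_queries < 0 or self.hits_per_query < 0 or self.n_articles < 0:
            raise ValueError("counts must be >= 0")
        if self.link_density < 0:
            raise ValueError("link_density must be >= 0")
        if not 0.0 <= self.accession_share_prob <= 1.0:
            raise ValueError("accession_share_prob must be in [0, 1]")
        for t in self.vocabulary:
            if not (0.0 <= t.occurrence_prob <= 1.0 and 0.0 <= t.major_prob <= 1.0):
                raise ValueError(f"term {t.name!r}: probabilities must be in [0, 1]")
        if self.planted and self.planted.n_target_queries > self.n_queries:
            raise ValueError("planted target subset larger than query set")


_JOURNALS = (
    "J Fish Biol", "Fish Shellfish Immunol", "Dev Comp Immunol",
    "Aquaculture", "J Virol", "BMC Genomics",
)

_TAXA = {
    7898: "Actinopterygii",
    8001: "Epinephelus coioides",
    8002: "Danio rerio",
    8003: "Oncorhynchus mykiss",
    8004: "Oryzias latipes",
    8005: "Paralichthys olivaceus",
}


@dataclass
class CorpusBundle:
    """The generated corpus as mutually consistent text blobs plus ground truth."""

    hit_table_text: str
    link_tsv: str
    article_tsv: str
    mesh_tree_tsv: str
    acc2tax_tsv: str
    tax_names_tsv: str
    ground_truth: dict = field(default_factory=dict)

    # -- parsed-object conveniences -------------------------------------
    def hit_table(self) -> HitTable:
        return parse_hit_table(self.hit_table_text, provenance="synthetic corpus")

    def link_map(self) -> LinkMap:
        return load_link_table(self.link_tsv)

    def article_store(self) -> ArticleStore:
        return load_article_tsv(self.article_tsv, provenance="synthetic corpus")

    def mesh_tree(self) -> MeshTreeMap:
        return load_mesh_tree(self.mesh_tree_tsv)

    def acc2tax(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for line in self.acc2tax_tsv.splitlines():
            if line:
                acc, taxid = line.split("\t")
                out[acc] = int(taxid)
        return out

    def tax_names(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for line in self.tax_names_tsv.splitlines():
            if line:
                taxid, name = line.split("\t")
                out[int(taxid)] = name
        return out

    _FILE_NAMES = {
        "hit_table_text": "hits.tsv",
        "link_tsv": "links.tsv",
        "article_tsv": "articles.tsv",
        "mesh_tree_tsv": "mesh_tree.tsv",
        "acc2tax_tsv": "acc2tax.tsv",
        "tax_names_tsv": "tax_names.tsv",
    }

    def write(self, out_dir: str) -> list[str]:
        """Write all bundle files (plus ground_truth.json) into a directory."""
        import json

        os.makedirs(out_dir, exist_ok=True)
        written = []
        for attr, fname in self._FILE_NAMES.items():
            path = os.path.join(out_dir, fname)
            with open(path, "w") as fh:
                fh.write(getattr(self, attr))
            written.append(path)
        path = os.path.join(out_dir, "ground_truth.json")
        with open(path, "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(path)
        return written


def _query_ids(n: int) -> list[str]:
    return [f"q{i:04d}" for i in range(1, n + 1)]


def generate_corpus(spec: CorpusSpec) -> CorpusBundle:
    """Generate one corpus, fully determined by ``spec`` (including its seed).

    Construction order: queries and their hit lists (one pseudo-accession
    per (query, rank), identities interpolated over ranks); a per-query
    article pool partitioning the article set; accession→article links drawn
    Poisson(link_density) from the owning query's pool; per-article term
    assignment (background vocabulary by per-term probability, the planted
    term by p_hi/p_lo according to the pool owner's target status).
    """
    rng = np.random.default_rng(spec.seed)
    queries = _query_ids(spec.n_queries)

    if spec.planted is not None:
        target = set(
            rng.choice(spec.n_queries, size=spec.planted.n_target_queries,
                       replace=False)
        )
        target_queries = {queries[i] for i in target}
    else:
        target_queries = set()

    # --- hits -----------------------------------------------------------
    start_id, end_id = spec.identity_decay
    hit_lines: list[str] = []
    accessions: list[tuple[str, str]] = []  # (accession, owner query)
    acc_of: dict[tuple[int, int], str] = {}
    for qi, q in enumerate(queries):
        for rank in range(1, spec.hits_per_query + 1):
            if (
                spec.accession_share_prob > 0
                and qi > 0
                and rng.random() < spec.accession_share_prob
            ):
                # re-use an accession from an earlier query at the same rank
                donor = int(rng.integers(0, qi))
                acc = acc_of[(donor, rank)]
            else:
                acc = f"XP_{qi + 1:04d}{rank:03d}.1"
            acc_of[(qi, rank)] = acc
            if spec.hits_per_query > 1:
                frac = (rank - 1) / (spec.hits_per_query - 1)
            else:
                frac = 0.0
            ident = start_id + (end_id - start_id) * frac
            if spec.identity_jitter:
                ident += float(rng.normal(0.0, spec.identity_jitter))
            ident = min(100.0, max(0.0, ident))
            evalue = 10.0 ** -(50.0 - 40.0 * frac)  # more significant at low rank
            bitscore = 500.0 - 400.0 * frac
            length = 200
            hit_lines.append(
                "\t".join(
                    (
                        q, acc, f"{ident:.3f}", str(length), "10", "2",
                        "1", str(length * 3), "1", str(length),
                        f"{evalue:.3g}", f"{bitscore:.1f}",
                    )
                )
            )
            accessions.append((acc, q))

    # --- article pools ---------------------------------------------------
    pmids = [100000 + i for i in range(1, spec.n_articles + 1)]
    pool_owner: dict[int, str] = {}
    if spec.n_queries > 0:
        for i, pmid in enumerate(pmids):
            pool_owner[pmid] = queries[i % spec.n_queries]
    pools: dict[str, list[int]] = {q: [] for q in queries}
    for pmid, owner in pool_owner.items():
        pools[owner].append(pmid)

    # --- links -----------------------------------------------------------
    links: dict[str, set[int]] = {}
    for acc, owner in accessions:
        bucket = links.setdefault(acc, set())
        pool = pools.get(owner, [])
        if not pool:
            continue
        n_links = int(rng.poisson(spec.link_density))
        n_links = min(n_links, len(pool))
        if n_links:
            chosen = rng.choice(len(pool), size=n_links, replace=False)
            bucket.update(pool[int(c)] for c in chosen)
    link_lines: list[str] = []
    for acc in sorted(links):
        if links[acc]:
            link_lines.extend(f"{acc}\t{p}" for p in sorted(links[acc]))
        else:
            link_lines.append(f"{acc}\t-")

    # --- articles --------------------------------------------------------
    article_lines = ["pmid\tjournal\tyear\tmajor\tminor"]
    for pmid in pmids:
        journal = _JOURNALS[int(rng.integers(0, len(_JOURNALS)))]
        year = int(rng.integers(2000, 2020))
        major: set[str] = set()
        minor: set[str] = set()
        for term in spec.vocabulary:
            if rng.random() < term.occurrence_prob:
                (major if rng.random() < term.major_prob else minor).add(term.name)
        if spec.planted is not None:
            owner = pool_owner.get(pmid)
            p = spec.planted.p_hi if owner in target_queries else spec.planted.p_lo
            if rng.random() < p:
                in_target_facet = rng.random() < spec.planted.facet_prob
                if (spec.planted.facet == "major") == in_target_facet:
                    major.add(spec.planted.term)
                else:
                    minor.add(spec.planted.term)
                minor -= major
        article_lines.append(
            f"{pmid}\t{journal}\t{year}\t"
            f"{';'.join(sorted(major))}\t{';'.join(sorted(minor))}"
        )

    # --- mesh tree -------------------------------------------------------
    tree_lines: list[str] = []
    for term in spec.vocabulary:
        tree_lines.extend(f"{term.name}\t{tn}" for tn in term.tree_numbers)
    if spec.planted is not None:
        tree_lines.extend(
            f"{spec.planted.term}\t{tn}" for tn in spec.planted.tree_numbers
        )

    # --- taxa ------------------------------------------------------------
    species = sorted(set(_TAXA) - {7898})
    acc2tax_lines = []
    for acc in sorted(links):
        taxid = species[int(rng.integers(0, len(species)))]
        acc2tax_lines.append(f"{acc}\t{taxid}")
    tax_name_lines = [f"{t}\t{n}" for t, n in sorted(_TAXA.items())]

    ground_truth = {
        "seed": spec.seed,
        "rng": RNG_ALGORITHM,
        "planted_term": spec.planted.term if spec.planted else None,
        "planted_facet": spec.planted.facet if spec.planted else None,
        "target_queries": sorted(target_queries),
        "queries": queries,
    }

    return CorpusBundle(
        hit_table_text="\n".join(hit_lines) + ("\n" if hit_lines else ""),
        link_tsv="\n".join(link_lines) + ("\n" if link_lines else ""),
        article_tsv="\n".join(article_lines) + "\n",
        mesh_tree_tsv="\n".join(tree_lines) + ("\n" if tree_lines else ""),
        acc2tax_tsv="\n".join(acc2tax_lines) + ("\n" if acc2tax_lines else ""),
        tax_names_tsv="\n".join(tax_name_lines) + "\n",
        ground_truth=ground_truth,
    )


def oracle_scores(
    bundle: CorpusBundle,
    facet: str,
    identity_floor: float = 40.0,
    evalue_cutoff: float = 1e-6,
    max_hits: int = 500,
) -> dict[str, tuple[float, int]]:
    """Naive reference computation of summed correlation scores.

    Re-derives per-term (total score, supporting-query count) straight from
    the bundle's text blobs with plain string splitting and an explicit
    triple loop (query → article → term). Shares no code with the scoring
    or parsing modules; exists solely as an independent cross-check.
    """
    # parse hits: query -> ordered deduplicated accession list, filtered
    per_query_accs: dict[str, list[str]] = {}
    for line in bundle.hit_table_text.splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        q, acc, pident, evalue = cols[0], cols[1], float(cols[2]), float(cols[10])
        accs = per_query_accs.setdefault(q, [])
        if pident < identity_floor or evalue > evalue_cutoff:
            continue
        if acc in accs:
            continue
        if len(accs) >= max_hits:
            continue
        accs.append(acc)

    # parse links: accession -> pmid set
    acc_links: dict[str, set[int]] = {}
    for line in bundle.link_tsv.splitlines():
        if not line:
            continue
        acc, pmid = line.split("\t")
        acc_links.setdefault(acc, set())
        if pmid != "-":
            acc_links[acc].add(int(pmid))

    # parse articles: pmid -> facet term set
    article_terms: dict[int, set[str]] = {}
    col = 3 if facet == "major" else 4
    for line in bundle.article_tsv.splitlines()[1:]:
        if not line:
            continue
        cols = line.split("\t")
        article_terms[int(cols[0])] = {t for t in cols[col].split(";") if t}

    totals: dict[str, float] = {}
    supporters: dict[str, set[str]] = {}
    for q in sorted(per_query_accs):
        pmid_set: set[int] = set()
        for acc in per_query_accs[q]:
            for pmid in acc_links.get(acc, ()):
                pmid_set.add(pmid)
        resolved = [p for p in sorted(pmid_set) if p in article_terms]
        if not resolved:
            continue
        term_counts: dict[str, int] = {}
        for pmid in resolved:
            for term in article_terms[pmid]:
                term_counts[term] = term_counts.get(term, 0) + 1
        for term, count in term_counts.items():
            totals[term] = totals.get(term, 0.0) + count / len(resolved)
            supporters.setdefault(term, set()).add(q)

    return {t: (totals[t], len(supporters[t])) for t in totals}
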
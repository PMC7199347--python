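# Methods

## The annotation model

`meshblast` annotates a de novo assembled contig by the literature of its
homologs rather than by transferred ontology tags. The pipeline is a chain
of set operations:

1. **Hits.** A translated BLAST search (blastx, fast task mode) of the
   contigs against a protein database yields a tabular hit file. Hits are
   trusted in BLAST's output order (descending bitscore) and never
   re-sorted, so truncating a query's list at rank *k* reproduces the
   effect of running BLAST with `max_target_seqs = k`.
2. **Filtering.** Per query, hits are dropped when percent identity is
   *strictly below* 40% (40.0 is kept) or the E-value *exceeds* 1e-6
   (exactly 1e-6 is kept, matching BLAST `-evalue` semantics, which retain
   alignments at the threshold). Subject accessions are deduplicated per
   query keeping the first (best-ranked) occurrence, because several HSPs
   against one subject must not link the same articles twice. Survivors are
   re-ranked 1..n and capped at 500 per query. Filtering runs before the
   cap, so low-identity hits never consume cap slots.
3. **Articles.** Each retained accession resolves to the PubMed IDs citing
   it (offline TSV backend, or Entrez ELink behind the same contract). A
   query's article set is the deduplicated union over its accessions; the
   same article counts independently for every query that reaches it.
4. **Scoring.** For query *q* with *n* resolvable articles, term *t* gets
   s(q,t) = (articles of *q* containing *t*) / *n*. A MeSH descriptor
   appears at most once per article, so s ∈ (0, 1] and equals 1 iff the
   term is in every article of the query. Global ranking is by
   Σ_q s(q,t). A direct consequence used as a standing invariant: a term's
   total score never exceeds its supporting-query count.
5. **Restriction.** The immune view filters the ranked major-facet list to
   terms with at least one MeSH tree number under A15 or G12. It is a pure
   subsequence restriction — no re-normalization — so scores are comparable
   across the overall and restricted tables.

### Assumptions

- BLAST hit order reflects alignment quality; we model hit depth purely by
  rank truncation.
- MeSH indexing is a meaningful proxy for what an article is about; the
  known biases of MeSH (indexing lag, vocabulary granularity) carry into
  the annotations.
- Scores are **descriptive**: they rank topical association and are not
  significance tests. No multiple-testing machinery applies.

## Parameter reference

| parameter | default | meaning |
|---|---|---|
| `evalue_cutoff` | 1e-6 | maximum E-value retained (inclusive) |
| `identity_floor_pct` | 40.0 | minimum percent identity retained (inclusive) |
| `max_hits_per_query` | 500 | hit-depth cap after filtering/dedup |
| `immune_categories` | {A15, G12} | MeSH tree prefixes of the restricted view |
| `top_n_major` / `top_n_minor` / `top_n_immune` | 20 / 10 / 10 | report-table lengths |
| depth grid | 1,5,10,25,50,100,200,300,400,500 | default sensitivity-scan depths |

The defaults are the method's published operating point; depth-scan users
typically find coverage saturating between 100 and 500 hits while mean hit
identity keeps falling, which is why the cap is a cap and not "more is
better".

## Major/minor partition

A MEDLINE heading contributes its descriptor to the **major** facet when
the descriptor or *any* attached qualifier carries `MajorTopicYN="Y"`;
otherwise to the **minor** facet. NLM frequently marks topical emphasis on
the qualifier only, so a descriptor-only rule would systematically
undercount major topics. Qualifier names themselves are never emitted as
terms. If one record repeats a descriptor with conflicting flags, major
wins, keeping the facets disjoint. Articles with no headings stay in the
store and count in the score denominator (they are retrieved evidence with
zero terms); PMIDs absent from the store are excluded from both numerator
and denominator. Publication year falls back to the first 4-digit year in
`MedlineDate`, else a 0 sentinel; year feeds no report.

## Category matching

Tree-number matching is dot-boundary aware: prefix `A15` matches `A15` and
`A15.x.y` but never `A150.x` or `A1.5`. Descriptor names are compared as
exact strings after whitespace stripping — MeSH is a controlled vocabulary,
so no further normalization is applied.

## Determinism and tie-breaking

Aggregation accumulates per-query scores in sorted query order (fixing
float summation order), and ranked output breaks score ties by
supporting-query count descending, then term name ascending. Shuffling
query or article order changes nothing. Distribution tables sort by count
descending then label ascending. TSV output displays scores to 2 decimals
and percentages to 1; the JSON evidence bundle keeps full precision and the
supporting-query IDs.

## Taxonomy subtrees

Subtree enumeration builds child lists in one pass and walks them with an
explicit stack, so multi-million-node taxonomy dumps cannot hit the
interpreter recursion limit. The root node is included in its own subtree:
the taxid list feeds sequence extraction, and sequences are attached at
internal ranks too. Merged/deleted taxids are the caller's responsibility
(supply a consistent dump).

## The synthetic corpus generator

`meshblast.synth` emulates the full input ensemble jointly: a hit table
(one pseudo-accession per query × rank, identities interpolated linearly
from 95% to 55% across ranks 1..10), an article pool of 250 articles
partitioned into per-query pools of 5, Poisson(1) links per accession into
the owning query's pool, a 30-term background vocabulary with per-article
occurrence probabilities between 0.02 and 0.20 and per-term major-topic
affinities, and a planted term appearing with probability 0.8 per article
in the pools of 20 target queries versus 0.05 elsewhere. All randomness
flows from one seeded PCG64 generator (`numpy.random.default_rng`), so a
spec+seed pair regenerates byte-identical bundles; the RNG identity is
recorded in the bundle's ground-truth block.

These sizes keep a 100-corpus sweep (generation, pipeline and oracle on
every seed, both facets) in the low seconds on one CPU while leaving the
planted signal (expected total score ≈ 17.5) well clear of the strongest
background term (≤ 10 in expectation).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequence content and real alignment statistics
(identities are a fixed decaying profile, not bitscore-driven), ELink's
spotty and bursty link coverage, MeSH vocabulary scale (tens of terms vs
~30k descriptors), inter-article term correlation, and shared hot articles
across unrelated queries (accession sharing exists but defaults off). The
identity-jitter default of 0 makes every query share one decay profile,
which is what makes pooled mean identity provably non-increasing in depth;
real tables only follow that trend statistically.

The scoring oracle (`oracle_scores`) recomputes summed scores from the
bundle's raw text with a plain triple loop and shares no code with the
pipeline; agreement is exact up to float summation (asserted at 1e-12).

## Numerical and degenerate-input choices

- Per-query scores are exact binary64 ratios count/n; sums over ≤ 50
  queries keep error far below the 1e-12 assertion level.
- Empty inputs are legal everywhere they are meaningful: an empty hit file
  parses to an empty table, a fully filtered query stays in the universe
  with an empty list, a query with no resolvable articles is simply
  unannotated. An empty taxid list is refused (an empty database filter is
  almost certainly a mistake), as is an empty or unsorted depth grid.
- Mean identity at a depth with zero surviving hits is `None`, not 0.

## Known limitations

- Annotation quality is bounded by literature coverage: a gene nobody has
  written about yields nothing, however deep the hit list.
- The "highly matched" taxonomic table counts one best hit per query;
  hit-level counting (which deep hit lists would dominate) is deliberately
  not offered.
- The journal table counts distinct pooled articles, describing the
  evidence corpus rather than citation intensity.
- The depth scan reports distinct-term counts, with term-occurrence tokens
  additionally exposed in JSON, since either reading of "term count" is
  defensible.
- Live ELink use is rate-limited (≤ 3 requests/s) but otherwise best
  effort; persistent backend failures abort loudly rather than silently
  dropping accessions.
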
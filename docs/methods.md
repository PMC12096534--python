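# Methods

## The model

The pipeline operates on document-level co-mention: a reference either
mentions an entity or it does not (mentions are sets, never multisets, and
title vs. abstract position is ignored). Genes and proteins are conflated
into one namespace keyed by the lowercased gene symbol, because literature
usage rarely distinguishes them and mentions usually lack organism
information; species resolution happens only through annotation tables
mapping a symbol to species-specific gene records (GID, taxon, preferred
name).

For entities A and B co-mentioned in c(A,B) of N references, the directed
raw score is

    S_raw(A → B) = c(A,B) · log_b(N / df(B)),     b = 10 by default,

a TF-IDF-family statistic: the co-mention count plays the term-frequency
role and the inverse document frequency of the *object* discounts
ubiquitous neighbors. Because only df(B) enters, the score is asymmetric,
which is exactly the behavior wanted for prioritized neighbor lists (a
rare entity is informative as a neighbor; a ubiquitous one is not). The
formula is a package default, injected as a callable (`raw_score_fn`), so
an alternative co-occurrence statistic — e.g. one with smoothing or
normalization — can be dropped in without touching counting, truncation,
serialization or queries.

Scores are serialized as non-negative integers S_CO = round(scale ·
S_raw) with scale = 100 and halves rounded away from zero. Each entity
keeps, per neighbor kind, a prioritized list truncated to the top k =
1000 entries. Both constants live in `ScoringParams` and flow through the
configuration layer unchanged.

### Ordering and ties

The graph stores only the serialized integer score, so any consumer
querying the RDF can order only by S_CO. To keep the in-memory neighbor
lists and the SPARQL view identical — including at the truncation
boundary — both are ordered by **serialized score descending, then object
IRI ascending**. Raw-score ordering can disagree with this only within a
rounding tie (raw values that serialize to the same integer), where the
stored data genuinely cannot distinguish the entries; determinism across
runs matters more there than an unobservable raw-score ranking. Reference
recency sorts use the completed calendar date with ties broken by
reference id descending.

### Dates

Year-only and year–month publication dates are completed to the first of
January / the first of the month, so recency sorting is total and
deterministic.

## IRIs

Compound and disease IRIs append `CID{n}` / `DZID{n}` to their namespace.
Gene IRIs use the lowercased symbol with selective percent-encoding:
letters and digits and the five exception characters `/ - _ : .` pass
through; everything else (including non-ASCII) is encoded as UTF-8 octets
with uppercase hex digits. `/` passing through produces multi-segment
paths; these stay parseable because the gene namespace is a known prefix.
Reified co-occurrence nodes concatenate subject and object tokens with
`_` (`CID3715_DZID8173`). CID/DZID tokens contain uppercase letters and
encoded gene tokens never do, so the leading token is unambiguous; for two
gene tokens the parser splits at the first `_`, which means a gene symbol
containing a literal underscore can be ambiguous *inside a co-occurrence
node IRI* (never as an entity IRI). Journal, author, grant and
organization nodes reuse the same encoder on their labels, giving
deterministic, collision-free metadata IRIs without counters.

## Serialization

Five triples per co-occurrence record: association class, provenance
marker, `rdf:subject`, `rdf:object`, and the integer score via
SIO_000300. Cross-kind association classes are the SIO terms
(chemical–disease SIO_000993, chemical–gene SIO_001257, gene–disease
SIO_000983); same-kind classes have no published term and default into
the vocabulary namespace (`vocab:CompoundCompoundCooccurrence`, ...), as
does the provenance marker (`vocab:TextMinedAssociation`) — all
overridable through `PredicateProfile`. Scores attach directly to the
co-occurrence node as `xsd:integer` literals (they are published as
integers). Reference metadata uses DCMI terms (title, date, creator,
isPartOf, subject), PRISM (publicationName, issn) and FRAPO
(isSupportedBy, hasGrantNumber, hasFundingAgency); the exact local names
are profile fields since only the vocabularies, not the property names,
are fixed by the model. A grant acknowledgment without a number becomes a
direct reference→agency triple; with a number, an indirect path through a
grant node. References additionally get an `rdf:type
vocab:PubMedReference`, which gives the SHACL reference shape a clean
target; reviews get a second type.

Triples are partitioned by the subject node's type into subdomains and
written one subdirectory each. A `book` subdomain is accepted in the
container but never produced (nothing in the model emits book nodes).
N-Triples output is canonically sorted line-by-line, making
byte-reproducibility testable; Turtle output relies on the underlying
serializer and is checked only for triple-set equality.

## Validation

The contract is emitted as SHACL: co-occurrence nodes need exactly one
subject, one object, one non-negative integer score, and at least one
type from the configured association-class set; references have at most
one title and date; entity IRIs reachable from co-occurrence or mention
triples must match the minting grammar (the gene alternative forbids bare
uppercase — uppercase may appear only inside percent escapes, whose hex
digits are uppercase by construction). Shape Expressions emission was
omitted: one machine-checkable contract suffices, and SHACL covers every
constraint stated by the model.

Validation runs on a focused SHACL-core validator implemented in this
package on top of rdflib. It supports precisely the constraint components
the emitted shapes use (target declarations, min/max cardinality,
datatype, minInclusive, pattern, nodeKind, qualified `sh:in` membership)
and reports the focus node, the violated component and the subdomain.
Six mutation operators (drop subject, drop object, duplicate score,
non-integer score, uppercase gene IRI, unknown association class) provide
the sensitivity catalog; each is guaranteed to produce a non-conformant
report, and soundness (serializer output always conforms) is property-
tested over random synthetic corpora.

## Queries

Each use-case operation substitutes its parameters into a SPARQL 1.1
template shipped as a text asset and runs it against the in-memory store;
brute-force record scans exist only as test oracles, so the tests exercise
the RDF model itself. Multi-gene operations assemble one triple block per
gene; the joint-mention count uses a subquery (candidate compounds) joined
against per-reference mention triples, so compounds without a single
joint reference drop out of the aggregation naturally. When the top gene
of the implicit-disease operation is tied, the tie-break ordering's first
gene is used. Unknown anchors yield empty results rather than errors,
matching SPARQL's open-world semantics. The templates assume the default
predicate profile (the SIO/vocab terms above); a custom profile requires
correspondingly adapted templates.

## Synthetic corpora

The generator emulates the statistical features the pipeline depends on:

- **Zipf-skewed marginals** (default exponent 1.1) within each kind's
  entity pool; pools of 120 compounds / 100 genes / 80 diseases at the
  default 500-reference size keep document frequencies in a realistic
  range (a few ubiquitous entities, a long rare tail).
- **Shifted-Poisson mention counts** (minimum 1, mean 4) — titles plus
  abstracts mention few entities.
- **Metadata**: dates spanning 2010–2023, twelve journals with ISSNs,
  finite author/agency/MeSH pools, review and PMC flags at configured
  rates (defaults 0.2 / 0.3), and a configured fraction (default 0.3) of
  references acknowledging an agency with no grant number.
- **Planted pairs**: with probability (enrichment − 1)·pA·pB per
  reference the pair is force-included, raising its joint frequency to
  about enrichment × the independence baseline. Forced inclusion also
  inflates the pair's marginals slightly, so the *observed* enrichment
  ratio c·N/(df(A)·df(B)) concentrates a little below the configured
  factor, and on a single corpus it carries Poisson noise; statistical
  checks therefore pool counts over several seeds.
- **Planted quadruples** are post-processed to appear in exactly the
  requested number of references (force-included in a sampled subset,
  and the compound removed from any other reference that would contain
  the full set).

What the generator does **not** model: real MeSH vocabulary, text-mining
errors (false positive/negative mentions), topical correlation between
entities beyond the planted associations, citation structure, or journal-
specific entity distributions. Green tests on synthetic data therefore
establish the pipeline's *mechanical* correctness (counting, scoring,
truncation, serialization, validation, query semantics) — not the
biological quality of co-occurrence mining on real literature.

## Problem sizes and numerical choices

The oracle-equivalence suites use twenty corpora of 150 references, and
planted-recovery checks twenty corpora of 600 references with the pair
planted on mid-rank entities at enrichment 5 — sizes at which brute-force
O(n·m²) scans remain instant while every code path (caps, ties, filters,
empty anchors) is exercised. The truncation demonstration uses 1500
distinct diseases against the k = 1000 cap, and the asymmetry
construction uses 1005 two-mention compounds plus one single-mention
compound around one ubiquitous disease, which provably pushes the rare
compound to rank 1006 of the disease's list. Rounding is half away from
zero everywhere a score is serialized. Empty corpora are rejected with a
dedicated error rather than returning empty maps, since every downstream
quantity (df, N) would be undefined.

## Known limitations

- Gene symbols containing `;` or tab characters cannot be written in the
  delimited corpus dialect (the writer rejects them loudly); symbols with
  `_` are valid everywhere except that co-occurrence node IRIs containing
  two such gene tokens may not parse back uniquely.
- The SHACL validator implements the core subset used by the emitted
  shapes, not the full recommendation (no SHACL-SPARQL, no closed
  shapes, no logical combinators beyond qualified `sh:in`).
- Journal deduplication is by exact name; no ISSN-based merging across
  corpora.
- Interoperability cross-references (skos:closeMatch etc. to external
  databases) and protein `encodedBy` extensions are out of scope.
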
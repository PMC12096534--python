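# coocrdf

Literature co-occurrence knowledge graphs for drug discovery, in RDF.

Biomedical references co-mention chemicals (compounds), genes/proteins and
diseases; which entities appear together in papers, and how often, is a
strong signal for association mining — finding the diseases discussed with
a drug, the compounds hitting several kinase genes, or the genes shared by
two comorbid diseases. `coocrdf` turns a document–mention table (one row
per reference, with bibliographic metadata and the set of entities found
in its title/abstract) into a queryable, validated RDF knowledge graph:

1. **Scoring.** For entities A, B co-mentioned in c(A,B) of N references,
   the directed co-occurrence score is a TF-IDF variant

   S_raw(A→B) = c(A,B) · log₁₀(N / df(B)),

   where df(B) is B's document frequency. The score discounts ubiquitous
   neighbors and is deliberately *asymmetric*: S(A→B) ≠ S(B→A). Scores are
   stored as integers S_CO = round(100 · S_raw). For every entity and every
   neighbor kind (compound, gene, disease), a prioritized list of up to
   1000 neighbors is kept; truncation makes neighborhood membership itself
   asymmetric (B can be in A's top-1000 while A misses B's).
2. **IRIs.** Compounds and diseases get `CID{n}` / `DZID{n}` local names;
   genes are identified by their lowercased symbol, with every character
   outside letters, digits and `/ - _ : .` percent-encoded as UTF-8 octets
   (`hoxa@` → `gene/hoxa%40`, `gamma ca1` → `gene/gamma%20ca1`).
3. **Serialization.** Each scored pair becomes a reified co-occurrence
   node carrying `rdf:subject`, `rdf:object`, an association class
   (SIO_000993 chemical–disease, SIO_001257 chemical–gene, SIO_000983
   gene–disease), a provenance marker, and its integer score via
   SIO_000300 ("has value"). References link to their mentions, journal,
   authors, grants (or directly to a funding agency when no grant number
   was acknowledged), MeSH headings, review/PMC flags. Triples are
   partitioned by *subdomain* — all triples sharing a subject-node type —
   and written one subdirectory each (Turtle or canonically sorted
   N-Triples).
4. **Validation.** The model contract is emitted as SHACL shapes
   (cardinalities on co-occurrence nodes, reference metadata, entity-IRI
   patterns) and every bundle can be checked against them.
5. **Querying.** Five literature-mining use cases ship as parametrized
   SPARQL templates run against an in-memory store: top neighbors,
   co-mentioning references, implicit disease associations via a shared
   gene, compounds co-mentioned with multiple genes (with FDA-approved-drug
   role filtering and joint-mention counting), and genes shared by two
   diseases (with human-gene name resolution).

A seeded synthetic-corpus generator (Zipf-skewed mention frequencies,
planted associations, realistic reference metadata) makes the whole
pipeline testable without any external download.

## Worked example

```sh
coocrdf generate  --seed 11 --n-refs 200 --out demo/data
coocrdf serialize --corpus demo/data/corpus.tsv \
                  --annotations demo/data/annotations \
                  --out demo/rdf --format ntriples
coocrdf validate  --bundle demo/rdf
coocrdf query --bundle demo/rdf top-neighbors \
              --anchor compound:1 --kind disease --limit 5
```

prints

```
conforms: true
disease:2	1077	Disease 2 (synthetic)
disease:32	547	Disease 32 (synthetic)
disease:1	526	Disease 1 (synthetic)
disease:3	450	Disease 3 (synthetic)
disease:66	400	Disease 66 (synthetic)
```

i.e. the five diseases most strongly associated with compound CID1 in the
200-reference synthetic corpus, with their serialized scores (S_CO; 1077
means S_raw ≈ 10.77) and preferred labels. Comorbidity mining works the
same way:

```sh
coocrdf query --bundle demo/rdf genes-for-diseases --d1 disease:1 --d2 disease:2
```

```
gamma ca1	GAMMA CA1 protein	511	409	920
bek6	BEK6 protein	419	280	699
...
```

one row per gene shared by both diseases' neighbor lists: symbol, human
preferred name, the two scores and their sum (the ranking key). The
`demo/rdf/` directory holds one subdirectory per subdomain (`cooccurrence`,
`reference`, `compound`, `gene`, `disease`, `journal`, `author`, `grant`,
`organization`).

The same operations are available as a library:

```python
from coocrdf import (SyntheticConfig, generate, build_neighbor_lists,
                     build_bundle, CooccurrenceStore, EntityRef)

records, annotations = generate(SyntheticConfig(n_refs=200, seed=11))
lists = build_neighbor_lists(records)          # scored, truncated at 1000
bundle = build_bundle(records, annotations, lists)
store = CooccurrenceStore.from_bundle(bundle)
store.top_neighbors(EntityRef.compound(1), "disease", limit=25)
```

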
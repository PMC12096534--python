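"""Seeded synthetic corpora with the statistical structure of literature
mention data.

Real title/abstract mention data is heavily skewed: a handful of entities
(think "neoplasms") appear in a large fraction of records while most
appear a handful of times.  The generator draws entity mentions from a
Zipf law (default exponent 1.1) within each kind, a shifted-Poisson
number of mentions per reference (titles and abstracts mention few
entities, default mean 4), and populates reference metadata -- dates
spanning 2010-2023, finite journal/author/agency pools, MeSH headings,
review and PMC flags, and a configurable fraction of grantless funding
acknowledgments.

Associations can be *planted*: a planted pair (A, B, enrichment) is
force-co-mentioned with extra probability ``(enrichment - 1) * pA * pB``
per reference, bringing its joint frequency to about ``enrichment`` times
the independence baseline while leaving the marginals near-Zipfian.
Planted quadruples (a compound plus a gene set) are made to co-occur in
*exactly* the requested number of references.

:func:`mutate_bundle` injects single, targeted schema defects into a
serialized bundle for validation-sensitivity testing.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdflib import Literal, URIRef
from rdflib.namespace import RDF, XSD

from .corpus_model import (
    EntityAnnotations,
    EntityKind,
    EntityRef,
    GeneRecord,
    Grant,
    ReferenceRecord,
)
from .rdf_serializer import GraphBundle, PredicateProfile
from .uri_minting import NamespaceTable, parse_entity_uri, mint_entity_uri

#: share of per-reference mention draws allotted to each kind
_KIND_MIX = {EntityKind.COMPOUND: 0.4, EntityKind.GENE: 0.3, EntityKind.DISEASE: 0.3}

#: gene symbols exercising the percent-encoding rules sit at the tail of the pool
_SPECIAL_SYMBOLS = ("hoxa@", "l(3)mbt", "gamma ca1", "il-6", "hla-drb1")

_JOURNALS = tuple(
    (f"Synth. J. {topic}", f"{1000 + 7 * i:04d}-{2000 + 13 * i:04d}")
    for i, topic in enumerate(
        ["Pharmacol.", "Oncol.", "Immunol.", "Chem. Biol.", "Genet.", "Med.",
         "Biochem.", "Neurosci.", "Cardiol.", "Microbiol.", "Pathol.", "Physiol."]
    )
)
_AGENCIES = ("NIH", "NSF", "Wellcome Trust", "ERC", "JSPS", "DFG")
_MESH_POOL = tuple(f"Heading {i:02d}" for i in range(30))
_AUTHOR_POOL = tuple(f"Author {i:02d} A." for i in range(40))


def _gene_symbol(i: int) -> str:
    if i < len(_SPECIAL_SYMBOLS):
        return _SPECIAL_SYMBOLS[i]
    consonants = "bcdfgklmnprstvz"
    vowels = "aeiou"
    return (
        consonants[i % len(consonants)]
        + vowels[(i // len(consonants)) % len(vowels)]
        + consonants[(i // 3) % len(consonants)]
        + str(i % 10 + 1)
    )


@dataclass(frozen=True)
class PlantedPair:
    a: EntityRef
    b: EntityRef
    enrichment: float

    def __post_init__(self) -> None:
        if self.enrichment <= 1:
            raise ValueError("enrichment must be > 1")


@dataclass(frozen=True)
class PlantedQuadruple:
    compound: EntityRef
    genes: tuple[EntityRef, ...]
    n_refs: int


@dataclass(frozen=True)
class SyntheticConfig:
    n_refs: int = 500
    n_compounds: int = 120
    n_genes: int = 100
    n_diseases: int = 80
    zipf_exponent: float = 1.1
    mean_mentions: float = 4.0
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_quadruples: tuple[PlantedQuadruple, ...] = ()
    review_fraction: float = 0.2
    pmc_fraction: float = 0.3
    grantless_agency_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("review_fraction", "pmc_fraction", "grantless_agency_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_refs < 1 or self.zipf_exponent <= 0 or self.mean_mentions < 1:
            raise ValueError("n_refs >= 1, zipf_exponent > 0, mean_mentions >= 1 required")
        for quad in self.planted_quadruples:
            if quad.n_refs > self.n_refs:
                raise ValueError(
                    f"cannot plant a quadruple in {quad.n_refs} of {self.n_refs} references"
                )


def entity_pool(config: SyntheticConfig, kind: EntityKind) -> list[EntityRef]:
    """The (seed-independent) entity pool for one kind, in Zipf-rank order."""
    if kind is EntityKind.COMPOUND:
        return [EntityRef.compound(i + 1) for i in range(config.n_compounds)]
    if kind is EntityKind.DISEASE:
        return [EntityRef.disease(i + 1) for i in range(config.n_diseases)]
    return [EntityRef.gene(_gene_symbol(i)) for i in range(config.n_genes)]


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = (np.arange(1, n + 1, dtype=float)) ** (-s)
    return w / w.sum()


def mention_probability(config: SyntheticConfig, e: EntityRef) -> float:
    """Approximate chance that entity ``e`` is mentioned in one reference."""
    pool = entity_pool(config, e.kind)
    rank = pool.index(e)
    w = _zipf_weights(len(pool), config.zipf_exponent)[rank]
    draws = config.mean_mentions * _KIND_MIX[e.kind]
    return float(1.0 - (1.0 - w) ** draws)


def generate(config: SyntheticConfig) -> tuple[list[ReferenceRecord], EntityAnnotations]:
    """Generate a corpus and its annotations; byte-deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    pools = {kind: entity_pool(config, kind) for kind in EntityKind}
    weights = {kind: _zipf_weights(len(pool), config.zipf_exponent)
               for kind, pool in pools.items()}
    kinds = list(_KIND_MIX)
    kind_p = np.array([_KIND_MIX[k] for k in kinds])
    plant_p = [
        (pp, (pp.enrichment - 1.0)
         * mention_probability(config, pp.a) * mention_probability(config, pp.b))
        for pp in config.planted_pairs
    ]

    mention_sets: list[set[EntityRef]] = []
    for _ in range(config.n_refs):
        m = 1 + rng.poisson(config.mean_mentions - 1.0)
        ments: set[EntityRef] = set()
        for kind_idx in rng.choice(len(kinds), size=m, p=kind_p):
            kind = kinds[kind_idx]
            idx = rng.choice(len(pools[kind]), p=weights[kind])
            ments.add(pools[kind][idx])
        for pp, p_extra in plant_p:
            if rng.random() < p_extra:
                ments |= {pp.a, pp.b}
        mention_sets.append(ments)

    # plant quadruples in exactly n_refs references
    for quad in config.planted_quadruples:
        members = {quad.compound, *quad.genes}
        chosen = set(rng.choice(config.n_refs, size=quad.n_refs, replace=False).tolist())
        for i, ments in enumerate(mention_sets):
            if i in chosen:
                ments |= members
            elif members <= ments:
                ments.discard(quad.compound)

    records: list[ReferenceRecord] = []
    for i, ments in enumerate(mention_sets):
        year = 2010 + int(rng.integers(0, 14))
        date = dt.date(year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        journal, issn = _JOURNALS[int(rng.integers(0, len(_JOURNALS)))]
        authors = tuple(
            _AUTHOR_POOL[j] for j in sorted(
                rng.choice(len(_AUTHOR_POOL), size=int(rng.integers(1, 5)), replace=False).tolist()
            )
        )
        grants: list[Grant] = []
        for _ in range(int(rng.integers(0, 3))):
            agency = _AGENCIES[int(rng.integers(0, len(_AGENCIES)))]
            grants.append(Grant(f"R{int(rng.integers(0, 100000)):05d}", agency))
        if rng.random() < config.grantless_agency_fraction:
            grants.append(Grant(None, _AGENCIES[int(rng.integers(0, len(_AGENCIES)))]))
        mesh = tuple(
            _MESH_POOL[j] for j in sorted(
                rng.choice(len(_MESH_POOL), size=int(rng.integers(0, 5)), replace=False).tolist()
            )
        )
        pmc_id = f"PMC{7000000 + i}" if rng.random() < config.pmc_fraction else None
        records.append(ReferenceRecord(
            ref_id=i + 1,
            title=f"Synthetic study {i + 1} of entity co-mentions",
            date=date,
            journal=journal,
            issn=issn,
            authors=authors,
            grants=tuple(grants),
            mesh_headings=mesh,
            is_review=bool(rng.random() < config.review_fraction),
            pmc_id=pmc_id,
            mentions=frozenset(ments),
        ))

    annotations = _make_annotations(config, rng)
    return records, annotations


def _make_annotations(config: SyntheticConfig, rng: np.random.Generator) -> EntityAnnotations:
    ann = EntityAnnotations()
    for d in entity_pool(config, EntityKind.DISEASE):
        ann.disease_labels[d.local_id] = f"Disease {d.local_id} (synthetic)"
    for c in entity_pool(config, EntityKind.COMPOUND):
        ann.compound_labels[c.local_id] = f"Compound {c.local_id} (synthetic)"
        roles = set()
        if rng.random() < 0.3:
            roles.add("FDAApprovedDrugs")
        if roles:
            ann.compound_roles[c.local_id] = frozenset(roles)
    taxa = (9606, 10090, 7955)  # human, mouse, zebrafish
    gid = 1
    gene_records: dict[str, list[GeneRecord]] = {}
    for g in entity_pool(config, EntityKind.GENE):
        recs = []
        has_human = rng.random() < 0.85
        for taxon in taxa if has_human else taxa[1:]:
            if taxon == 9606 or rng.random() < 0.4:
                recs.append(GeneRecord(gid, taxon, f"{g.local_id.upper()} protein"))
                gid += 1
        if not recs:
            recs.append(GeneRecord(gid, taxa[1], f"{g.local_id.upper()} protein"))
            gid += 1
        gene_records[g.local_id] = recs
    ann.gene_records = {s: tuple(rs) for s, rs in gene_records.items()}
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# Defect injection for validation-sensitivity testing
# ---------------------------------------------------------------------------

MUTATION_OPERATORS = (
    "drop_subject",
    "drop_object",
    "duplicate_score",
    "non_integer_score",
    "uppercase_gene_iri",
    "unknown_association_class",
)


class MutationError(ValueError):
    pass


def mutate_bundle(bundle: GraphBundle, operator: str, seed: int = 0,
                  profile: PredicateProfile | None = None) -> GraphBundle:
    """Return a copy of ``bundle`` differing by exactly one injected defect."""
    if operator not in MUTATION_OPERATORS:
        raise MutationError(f"unknown mutation operator {operator!r}")
    profile = profile or PredicateProfile.default(bundle.ns)
    out = bundle.copy()
    g = out.graphs.get("cooccurrence")
    if g is None or len(g) == 0:
        raise MutationError("bundle has no co-occurrence triples to mutate")
    rng = np.random.default_rng(seed)
    nodes = sorted(set(g.subjects(RDF.subject, None)), key=str)
    if not nodes:
        raise MutationError("no reified co-occurrence nodes present")

    def pick(candidates):
        if not candidates:
            raise MutationError(f"operator {operator!r} is inapplicable to this bundle")
        return candidates[int(rng.integers(0, len(candidates)))]

    if operator == "drop_subject":
        node = pick(nodes)
        g.remove((node, RDF.subject, None))
    elif operator == "drop_object":
        node = pick(nodes)
        g.remove((node, RDF.object, None))
    elif operator == "duplicate_score":
        node = pick(nodes)
        value = g.value(node, profile.score_predicate)
        g.add((node, profile.score_predicate,
               Literal(int(value) + 1, datatype=XSD.integer)))
    elif operator == "non_integer_score":
        node = pick(nodes)
        value = g.value(node, profile.score_predicate)
        g.remove((node, profile.score_predicate, None))
        g.add((node, profile.score_predicate,
               Literal(float(int(value)) + 0.5, datatype=XSD.decimal)))
    elif operator == "uppercase_gene_iri":
        gene_base = bundle.ns["gene"]
        candidates = sorted(
            {(n, o) for pred in (RDF.subject, RDF.object)
             for n, o in g.subject_objects(pred)
             if str(o).startswith(gene_base) and any(c.islower() for c in str(o))},
            key=lambda pair: (str(pair[0]), str(pair[1])),
        )
        node, obj = pick(candidates)
        upper = URIRef(gene_base + str(obj)[len(gene_base):].upper())
        for pred in (RDF.subject, RDF.object):
            if (node, pred, obj) in g:
                g.remove((node, pred, obj))
                g.add((node, pred, upper))
                break
    elif operator == "unknown_association_class":
        allowed = set(profile.association_classes.values())
        candidates = sorted(
            {(n, o) for n, o in g.subject_objects(RDF.type) if o in allowed},
            key=lambda pair: (str(pair[0]), str(pair[1])),
        )
        node, cls = pick(candidates)
        g.remove((node, RDF.type, cls))
        g.add((node, RDF.type, URIRef(bundle.ns["vocab"] + "UnknownAssociation")))
    return out
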
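"""RDF serialization of the co-occurrence graph, partitioned by subdomain.

The graph has five families of nodes: named entities (compounds, genes,
diseases), references and their metadata (journal, author, grant, funding
organization), and the reified co-occurrence nodes.  Each co-occurrence
record becomes exactly five triples with the default profile::

    node rdf:type      <association class>      # e.g. sio:SIO_000993
    node rdf:type      <provenance marker>      # text-mining derived
    node rdf:subject   <subject entity IRI>
    node rdf:object    <object entity IRI>
    node sio:SIO_000300 "<serialized score>"^^xsd:integer

Triples are partitioned by *subdomain*: all triples sharing the same
subject-node type go together (cooccurrence, reference, compound, gene,
disease, journal, author, grant, organization), and each non-empty
subdomain is written to its own subdirectory, mirroring how large
triplestore dumps are published for selective download.

Predicate and class choices that the model leaves open (same-kind
association classes, reference-metadata local names, the provenance
marker) default into the PubChem-style ``vocab:`` namespace and are
overridable through :class:`PredicateProfile`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, XSD

from .corpus_model import EntityAnnotations, EntityKind, EntityRef, ReferenceRecord
from .scoring import CooccurrenceRecord, NeighborList, PAIR_CLASSES
from .uri_minting import (
    NamespaceTable,
    mint_cooccurrence_uri,
    mint_entity_uri,
    percent_encode,
)


class SerializationError(ValueError):
    pass


SUBDOMAINS = (
    "cooccurrence", "reference", "compound", "gene", "disease",
    "journal", "author", "grant", "organization", "book",
)


@dataclass(frozen=True)
class PredicateProfile:
    """The predicates and classes used when emitting triples.

    Cross-kind association classes follow the Semanticscience Integrated
    Ontology (chemical-disease SIO_000993, chemical-gene SIO_001257,
    gene-disease SIO_000983); same-kind classes have no published term
    and default into the vocabulary namespace.
    """

    association_classes: Mapping[str, URIRef]
    provenance_marker: URIRef
    score_predicate: URIRef
    mention_predicate: URIRef
    reference_class: URIRef
    review_class: URIRef
    title_predicate: URIRef
    date_predicate: URIRef
    journal_link_predicate: URIRef
    journal_name_predicate: URIRef
    issn_predicate: URIRef
    author_link_predicate: URIRef
    label_predicate: URIRef
    grant_link_predicate: URIRef
    grant_number_predicate: URIRef
    agency_predicate: URIRef
    mesh_predicate: URIRef
    pmc_predicate: URIRef
    role_predicate: URIRef
    gene_symbol_predicate: URIRef
    organism_predicate: URIRef

    @classmethod
    def default(cls, ns: NamespaceTable | None = None) -> "PredicateProfile":
        ns = ns or NamespaceTable()
        sio, vocab, obo = ns["sio"], ns["vocab"], ns["obo"]
        dcterms, prism, frapo = ns["dcterms"], ns["prism"], ns["frapo"]
        return cls(
            association_classes={
                "compound-disease": URIRef(sio + "SIO_000993"),
                "compound-gene": URIRef(sio + "SIO_001257"),
                "gene-disease": URIRef(sio + "SIO_000983"),
                "compound-compound": URIRef(vocab + "CompoundCompoundCooccurrence"),
                "gene-gene": URIRef(vocab + "GeneGeneCooccurrence"),
                "disease-disease": URIRef(vocab + "DiseaseDiseaseCooccurrence"),
            },
            provenance_marker=URIRef(vocab + "TextMinedAssociation"),
            score_predicate=URIRef(sio + "SIO_000300"),
            mention_predicate=URIRef(vocab + "discussesAsDerivedByTextMining"),
            reference_class=URIRef(vocab + "PubMedReference"),
            review_class=URIRef(vocab + "ReviewArticle"),
            title_predicate=URIRef(dcterms + "title"),
            date_predicate=URIRef(dcterms + "date"),
            journal_link_predicate=URIRef(dcterms + "isPartOf"),
            journal_name_predicate=URIRef(prism + "publicationName"),
            issn_predicate=URIRef(prism + "issn"),
            author_link_predicate=URIRef(dcterms + "creator"),
            label_predicate=URIRef(ns["skos"] + "prefLabel"),
            grant_link_predicate=URIRef(frapo + "isSupportedBy"),
            grant_number_predicate=URIRef(frapo + "hasGrantNumber"),
            agency_predicate=URIRef(frapo + "hasFundingAgency"),
            mesh_predicate=URIRef(dcterms + "subject"),
            pmc_predicate=URIRef(vocab + "hasPMCId"),
            role_predicate=URIRef(obo + "RO_0000087"),
            gene_symbol_predicate=URIRef(ns["bao"] + "BAO_0002870"),
            organism_predicate=URIRef(ns["up"] + "organism"),
        )

    def with_overrides(self, **kwargs) -> "PredicateProfile":
        return replace(self, **kwargs)


class GraphBundle:
    """Triples partitioned by subdomain (one :class:`rdflib.Graph` each)."""

    def __init__(self, ns: NamespaceTable | None = None) -> None:
        self.ns = ns or NamespaceTable()
        self.graphs: dict[str, Graph] = {}

    def graph(self, subdomain: str) -> Graph:
        if subdomain not in SUBDOMAINS:
            raise SerializationError(f"unknown subdomain {subdomain!r}")
        if subdomain not in self.graphs:
            g = Graph()
            self.ns.bind(g)
            self.graphs[subdomain] = g
        return self.graphs[subdomain]

    def union(self) -> Graph:
        g = Graph()
        self.ns.bind(g)
        for sub in self.graphs.values():
            for triple in sub:
                g.add(triple)
        return g

    def triple_count(self) -> int:
        return sum(len(g) for g in self.graphs.values())

    def subdomain_of(self, node) -> str | None:
        for name, g in self.graphs.items():
            if (node, None, None) in g:
                return name
        return None

    def merge(self, other: "GraphBundle") -> "GraphBundle":
        for name, g in other.graphs.items():
            dest = self.graph(name)
            for triple in g:
                dest.add(triple)
        return self

    def copy(self) -> "GraphBundle":
        out = GraphBundle(self.ns)
        return out.merge(self)

    def triple_set(self) -> set:
        out: set = set()
        for g in self.graphs.values():
            out |= set(g)
        return out


# ---------------------------------------------------------------------------
# Node IRI helpers for metadata entities
# ---------------------------------------------------------------------------

def reference_uri(ref_id: int, ns: NamespaceTable) -> URIRef:
    return URIRef(ns["reference"] + f"PMID{ref_id}")


def _labelled_uri(base: str, label: str) -> URIRef:
    return URIRef(base + percent_encode(label))


def taxonomy_uri(taxon_id: int, ns: NamespaceTable) -> URIRef:
    return URIRef(ns["taxonomy"] + f"TAXID{taxon_id}")


def gene_record_uri(gid: int, ns: NamespaceTable) -> URIRef:
    return URIRef(ns["gene"] + f"GID{gid}")


# ---------------------------------------------------------------------------
# Serializers
# ---------------------------------------------------------------------------

def serialize_cooccurrences(lists: Mapping[tuple[EntityRef, EntityKind], NeighborList],
                            profile: PredicateProfile | None = None,
                            ns: NamespaceTable | None = None) -> GraphBundle:
    """Emit the reified co-occurrence nodes: 5 triples per record."""
    ns = ns or NamespaceTable()
    profile = profile or PredicateProfile.default(ns)
    bundle = GraphBundle(ns)
    g = bundle.graph("cooccurrence")
    for key in sorted(lists, key=lambda k: (k[0].sort_key, k[1].value)):
        for rec in lists[key].entries:
            cls = profile.association_classes.get(rec.pair_class)
            if cls is None:
                raise SerializationError(
                    f"no association class configured for pair class {rec.pair_class!r}"
                )
            node = URIRef(mint_cooccurrence_uri(rec.subject, rec.object, ns))
            g.add((node, RDF.type, cls))
            g.add((node, RDF.type, profile.provenance_marker))
            g.add((node, RDF.subject, URIRef(mint_entity_uri(rec.subject, ns))))
            g.add((node, RDF.object, URIRef(mint_entity_uri(rec.object, ns))))
            g.add((node, profile.score_predicate,
                   Literal(rec.serialized_score, datatype=XSD.integer)))
    return bundle


def serialize_references(refs: Sequence[ReferenceRecord],
                         profile: PredicateProfile | None = None,
                         ns: NamespaceTable | None = None) -> GraphBundle:
    """Emit reference nodes, their mention links and their metadata.

    A grant acknowledgment with a number yields an indirect path
    reference -> grant -> agency; a grantless acknowledgment yields a
    direct reference -> agency triple instead.
    """
    ns = ns or NamespaceTable()
    profile = profile or PredicateProfile.default(ns)
    bundle = GraphBundle(ns)
    g_ref = bundle.graph("reference")
    for rec in sorted(refs, key=lambda r: r.ref_id):
        node = reference_uri(rec.ref_id, ns)
        g_ref.add((node, RDF.type, profile.reference_class))
        if rec.is_review:
            g_ref.add((node, RDF.type, profile.review_class))
        g_ref.add((node, profile.title_predicate, Literal(rec.title)))
        g_ref.add((node, profile.date_predicate, Literal(rec.date, datatype=XSD.date)))
        for ment in sorted(rec.mentions, key=lambda e: e.sort_key):
            g_ref.add((node, profile.mention_predicate, URIRef(mint_entity_uri(ment, ns))))
        jnode = _labelled_uri(ns["journal"], rec.journal)
        g_ref.add((node, profile.journal_link_predicate, jnode))
        g_j = bundle.graph("journal")
        g_j.add((jnode, profile.journal_name_predicate, Literal(rec.journal)))
        if rec.issn:
            g_j.add((jnode, profile.issn_predicate, Literal(rec.issn)))
        for author in rec.authors:
            anode = _labelled_uri(ns["author"], author)
            g_ref.add((node, profile.author_link_predicate, anode))
            bundle.graph("author").add((anode, profile.label_predicate, Literal(author)))
        for grant in rec.grants:
            orgnode = _labelled_uri(ns["organization"], grant.agency)
            bundle.graph("organization").add(
                (orgnode, profile.label_predicate, Literal(grant.agency)))
            if grant.number is None:
                g_ref.add((node, profile.agency_predicate, orgnode))
            else:
                gnode = _labelled_uri(ns["grant"], grant.number)
                g_ref.add((node, profile.grant_link_predicate, gnode))
                g_g = bundle.graph("grant")
                g_g.add((gnode, profile.grant_number_predicate, Literal(grant.number)))
                g_g.add((gnode, profile.agency_predicate, orgnode))
        for heading in rec.mesh_headings:
            g_ref.add((node, profile.mesh_predicate, Literal(heading)))
        if rec.pmc_id:
            g_ref.add((node, profile.pmc_predicate, Literal(rec.pmc_id)))
    return bundle


def serialize_entities(annotations: EntityAnnotations,
                       profile: PredicateProfile | None = None,
                       ns: NamespaceTable | None = None) -> GraphBundle:
    """Emit entity annotation triples (labels, gene records, roles)."""
    ns = ns or NamespaceTable()
    profile = profile or PredicateProfile.default(ns)
    annotations.validate()
    bundle = GraphBundle(ns)
    g_d = bundle.graph("disease")
    for dzid, label in sorted(annotations.disease_labels.items(), key=lambda kv: int(kv[0])):
        node = URIRef(mint_entity_uri(EntityRef.disease(dzid), ns))
        g_d.add((node, profile.label_predicate, Literal(label)))
    g_g = bundle.graph("gene")
    for symbol, records in sorted(annotations.gene_records.items()):
        symbol_node = URIRef(mint_entity_uri(EntityRef.gene(symbol), ns))
        for rec in records:
            gid_node = gene_record_uri(rec.gene_record_id, ns)
            g_g.add((gid_node, profile.gene_symbol_predicate, symbol_node))
            g_g.add((gid_node, profile.organism_predicate, taxonomy_uri(rec.taxon_id, ns)))
            g_g.add((gid_node, profile.label_predicate, Literal(rec.preferred_name)))
    g_c = bundle.graph("compound")
    for cid, roles in sorted(annotations.compound_roles.items(), key=lambda kv: int(kv[0])):
        node = URIRef(mint_entity_uri(EntityRef.compound(cid), ns))
        for role in sorted(roles):
            g_c.add((node, profile.role_predicate, URIRef(ns["vocab"] + role)))
    for cid, label in sorted(annotations.compound_labels.items(), key=lambda kv: int(kv[0])):
        node = URIRef(mint_entity_uri(EntityRef.compound(cid), ns))
        g_c.add((node, profile.label_predicate, Literal(label)))
    return bundle


def build_bundle(records: Sequence[ReferenceRecord],
                 annotations: EntityAnnotations,
                 lists: Mapping[tuple[EntityRef, EntityKind], NeighborList],
                 profile: PredicateProfile | None = None,
                 ns: NamespaceTable | None = None) -> GraphBundle:
    """Serialize the whole model into one partitioned bundle."""
    ns = ns or NamespaceTable()
    profile = profile or PredicateProfile.default(ns)
    bundle = serialize_cooccurrences(lists, profile, ns)
    bundle.merge(serialize_references(records, profile, ns))
    bundle.merge(serialize_entities(annotations, profile, ns))
    return bundle


# ---------------------------------------------------------------------------
# Writers / readers
# ---------------------------------------------------------------------------

_EXT = {"turtle": ".ttl", "ntriples": ".nt"}


def _canonical_ntriples(g: Graph) -> str:
    lines = sorted(
        f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in g
    )
    return "\n".join(lines) + ("\n" if lines else "")


def write_bundle(bundle: GraphBundle, directory: str | Path,
                 format: str = "turtle") -> list[Path]:
    """One file per non-empty subdomain, in its own subdirectory.

    N-Triples output is canonically sorted so identical bundles produce
    byte-identical files.
    """
    if format not in _EXT:
        raise SerializationError(f"unknown output format {format!r}")
    directory = Path(directory)
    written: list[Path] = []
    for name in SUBDOMAINS:
        g = bundle.graphs.get(name)
        if g is None or len(g) == 0:
            continue
        subdir = directory / name
        subdir.mkdir(parents=True, exist_ok=True)
        path = subdir / f"{name}{_EXT[format]}"
        if format == "ntriples":
            path.write_text(_canonical_ntriples(g), encoding="utf-8")
        else:
            g.serialize(destination=str(path), format="turtle")
        written.append(path)
    return written


def read_bundle(directory: str | Path, ns: NamespaceTable | None = None) -> GraphBundle:
    """Re-parse a written bundle; the union reproduces the triple set."""
    directory = Path(directory)
    bundle = GraphBundle(ns)
    for name in SUBDOMAINS:
        subdir = directory / name
        if not subdir.is_dir():
            continue
        for path in sorted(subdir.iterdir()):
            if path.suffix == ".ttl":
                bundle.graph(name).parse(str(path), format="turtle")
            elif path.suffix == ".nt":
                bundle.graph(name).parse(str(path), format="nt")
    return bundle
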
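"""SHACL shapes for the co-occurrence graph, and a validator for them.

:func:`emit_shapes` writes the model contract as a SHACL shapes graph:

* every co-occurrence node carries exactly one ``rdf:subject``, exactly
  one ``rdf:object``, exactly one non-negative ``xsd:integer`` score, and
  at least one ``rdf:type`` drawn from the configured association-class
  set;
* every reference node has at most one title and one date;
* every entity IRI reachable from a co-occurrence or mention triple
  matches the minting conventions -- ``CID`` + digits for compounds,
  ``DZID`` + digits for diseases, and a gene path containing no bare
  uppercase characters (uppercase may appear only inside percent
  escapes).

:func:`validate` checks a graph bundle against a shapes graph.  It
implements the SHACL-core subset those shapes use -- target declarations
(``sh:targetClass``, ``sh:targetSubjectsOf``, ``sh:targetObjectsOf``),
cardinalities, ``sh:datatype``, ``sh:minInclusive``, ``sh:pattern``,
``sh:nodeKind`` and qualified ``sh:in`` membership -- and reports one
violation per failed constraint, naming the focus node and its subdomain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.collection import Collection
from rdflib.namespace import RDF, SH, XSD

from .rdf_serializer import GraphBundle, PredicateProfile
from .uri_minting import NamespaceTable


class ValidationInputError(ValueError):
    pass


SHAPES_BASE = "http://rdf.ncbi.nlm.nih.gov/pubchem/shapes/"


@dataclass
class ShapeSet:
    """A parseable SHACL shapes graph."""

    graph: Graph

    def serialize(self, path=None) -> str | None:
        if path is None:
            return self.graph.serialize(format="turtle")
        self.graph.serialize(destination=str(path), format="turtle")
        return None


def _property(g: Graph, shape: URIRef, path: URIRef, **constraints) -> None:
    ps = BNode()
    g.add((shape, SH.property, ps))
    g.add((ps, SH.path, path))
    for key, value in constraints.items():
        g.add((ps, getattr(SH, key), value))


def entity_iri_pattern(ns: NamespaceTable) -> str:
    """Anchored regex accepting exactly the three entity IRI forms."""
    return (
        "^(?:"
        + re.escape(ns["compound"]) + "CID[0-9]+"
        + "|" + re.escape(ns["disease"]) + "DZID[0-9]+"
        + "|" + re.escape(ns["gene"]) + "(?:[^A-Z%]|%[0-9A-F]{2})+"
        + ")$"
    )


def emit_shapes(profile: PredicateProfile | None = None,
                ns: NamespaceTable | None = None) -> ShapeSet:
    ns = ns or NamespaceTable()
    profile = profile or PredicateProfile.default(ns)
    g = Graph()
    ns.bind(g)
    g.bind("sh", SH)
    g.bind("shapes", SHAPES_BASE)

    co = URIRef(SHAPES_BASE + "CooccurrenceShape")
    g.add((co, RDF.type, SH.NodeShape))
    g.add((co, SH.targetSubjectsOf, RDF.subject))
    g.add((co, SH.targetSubjectsOf, RDF.object))
    one = Literal(1)
    _property(g, co, RDF.subject, minCount=one, maxCount=one, nodeKind=SH.IRI)
    _property(g, co, RDF.object, minCount=one, maxCount=one, nodeKind=SH.IRI)
    _property(g, co, profile.score_predicate, minCount=one, maxCount=one,
              datatype=XSD.integer, minInclusive=Literal(0))
    classes = BNode()
    Collection(g, classes, sorted(set(profile.association_classes.values())))
    qshape = BNode()
    g.add((qshape, SH["in"], classes))
    ps = BNode()
    g.add((co, SH.property, ps))
    g.add((ps, SH.path, RDF.type))
    g.add((ps, SH.qualifiedValueShape, qshape))
    g.add((ps, SH.qualifiedMinCount, one))

    ref = URIRef(SHAPES_BASE + "ReferenceShape")
    g.add((ref, RDF.type, SH.NodeShape))
    g.add((ref, SH.targetClass, profile.reference_class))
    _property(g, ref, profile.title_predicate, maxCount=one)
    _property(g, ref, profile.date_predicate, maxCount=one)

    ent = URIRef(SHAPES_BASE + "EntityIriShape")
    g.add((ent, RDF.type, SH.NodeShape))
    g.add((ent, SH.targetObjectsOf, RDF.subject))
    g.add((ent, SH.targetObjectsOf, RDF.object))
    g.add((ent, SH.targetObjectsOf, profile.mention_predicate))
    g.add((ent, SH.nodeKind, SH.IRI))
    g.add((ent, SH.pattern, Literal(entity_iri_pattern(ns))))

    return ShapeSet(g)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    focus: str
    constraint: str
    message: str


@dataclass
class ConformanceReport:
    conforms: bool
    violations: list[Violation]

    def __str__(self) -> str:
        if self.conforms:
            return "conforms: true"
        lines = [f"conforms: false ({len(self.violations)} violations)"]
        lines += [f"  [{v.constraint}] {v.focus}: {v.message}" for v in self.violations]
        return "\n".join(lines)


def _targets(shapes: Graph, shape, data: Graph) -> set:
    focuses: set = set()
    for cls in shapes.objects(shape, SH.targetClass):
        focuses |= set(data.subjects(RDF.type, cls))
    for pred in shapes.objects(shape, SH.targetSubjectsOf):
        focuses |= set(data.subjects(pred, None))
    for pred in shapes.objects(shape, SH.targetObjectsOf):
        focuses |= set(data.objects(None, pred))
    return focuses


def validate(bundle: GraphBundle, shapes: ShapeSet) -> ConformanceReport:
    """Check every node shape's targets; sound on serializer output."""
    if not isinstance(shapes.graph, Graph):
        raise ValidationInputError("shapes must wrap a parsed RDF graph")
    data = bundle.union()
    violations: list[Violation] = []

    def where(node) -> str:
        sub = bundle.subdomain_of(node)
        return f"in subdomain {sub!r}" if sub else "subdomain unknown"

    def report(focus, constraint: str, message: str) -> None:
        violations.append(Violation(str(focus), constraint, f"{message} ({where(focus)})"))

    sg = shapes.graph
    for shape in sorted(sg.subjects(RDF.type, SH.NodeShape)):
        focuses = _targets(sg, shape, data)
        node_kind = sg.value(shape, SH.nodeKind)
        node_pattern = sg.value(shape, SH.pattern)
        compiled = re.compile(str(node_pattern)) if node_pattern is not None else None
        for focus in sorted(focuses, key=str):
            if node_kind == SH.IRI and not isinstance(focus, URIRef):
                report(focus, "nodeKind", "expected an IRI node")
            if compiled is not None and isinstance(focus, URIRef) \
                    and not compiled.search(str(focus)):
                report(focus, "pattern",
                       f"IRI does not match entity pattern {node_pattern}")
            for pshape in sg.objects(shape, SH.property):
                _check_property(sg, pshape, data, focus, report)
    return ConformanceReport(conforms=not violations, violations=violations)


def _check_property(sg: Graph, pshape, data: Graph, focus, report) -> None:
    path = sg.value(pshape, SH.path)
    if path is None:
        return
    values = list(data.objects(focus, path))
    min_count = sg.value(pshape, SH.minCount)
    if min_count is not None and len(values) < int(min_count):
        report(focus, "minCount", f"needs >= {min_count} values for {path}, has {len(values)}")
    max_count = sg.value(pshape, SH.maxCount)
    if max_count is not None and len(values) > int(max_count):
        report(focus, "maxCount", f"allows <= {max_count} values for {path}, has {len(values)}")
    datatype = sg.value(pshape, SH.datatype)
    if datatype is not None:
        for v in values:
            if not isinstance(v, Literal) or v.datatype != datatype:
                report(focus, "datatype", f"value {v.n3()} for {path} is not ^^{datatype}")
    min_inclusive = sg.value(pshape, SH.minInclusive)
    if min_inclusive is not None:
        for v in values:
            try:
                ok = v.toPython() >= min_inclusive.toPython()
            except (AttributeError, TypeError):
                ok = False
            if not ok:
                report(focus, "minInclusive", f"value {v.n3()} for {path} below {min_inclusive}")
    pattern = sg.value(pshape, SH.pattern)
    if pattern is not None:
        compiled = re.compile(str(pattern))
        for v in values:
            if not compiled.search(str(v)):
                report(focus, "pattern", f"value {v} for {path} fails {pattern}")
    node_kind = sg.value(pshape, SH.nodeKind)
    if node_kind == SH.IRI:
        for v in values:
            if not isinstance(v, URIRef):
                report(focus, "nodeKind", f"value {v.n3()} for {path} is not an IRI")
    qshape = sg.value(pshape, SH.qualifiedValueShape)
    if qshape is not None:
        qmin = sg.value(pshape, SH.qualifiedMinCount)
        members_node = sg.value(qshape, SH["in"])
        allowed = set(Collection(sg, members_node)) if members_node is not None else set()
        matching = [v for v in values if v in allowed]
        if qmin is not None and len(matching) < int(qmin):
            report(focus, "qualifiedMinCount",
                   f"needs >= {qmin} values of {path} from the configured class set, "
                   f"has {len(matching)}")
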
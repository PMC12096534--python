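import pytest
from rdflib import URIRef
from rdflib.namespace import RDF, XSD

from coocrdf import (
    EntityAnnotations,
    EntityKind,
    EntityRef,
    GeneRecord,
    Grant,
    NamespaceTable,
    PredicateProfile,
    build_neighbor_lists,
    build_bundle,
    parse_cooccurrence_uri,
    read_bundle,
    serialize_cooccurrences,
    serialize_entities,
    serialize_references,
    write_bundle,
)
from coocrdf.rdf_serializer import SerializationError

from conftest import make_record

NS = NamespaceTable()
PROFILE = PredicateProfile.default(NS)
C, D, G = EntityRef.compound, EntityRef.disease, EntityRef.gene


def _lists(corpus):
    return build_neighbor_lists(corpus)


class TestCooccurrenceTriples:
    def test_five_triples_per_record(self):
        corpus = [make_record(i, {C(1), D(i % 3 + 1)}) for i in range(1, 8)]
        lists = _lists(corpus)
        n_records = sum(len(nl.entries) for nl in lists.values())
        bundle = serialize_cooccurrences(lists, PROFILE, NS)
        assert len(bundle.graphs["cooccurrence"]) == 5 * n_records

    def test_pair_class_typing(self):
        corpus = [make_record(1, {C(1), D(1)}), make_record(2, {C(1), D(1), C(2)})]
        g = serialize_cooccurrences(_lists(corpus), PROFILE, NS).graphs["cooccurrence"]
        node = URIRef(NS["cooccurrence"] + "CID1_DZID1")
        types = set(g.objects(node, RDF.type))
        assert URIRef(NS["sio"] + "SIO_000993") in types       # chemical-disease
        assert PROFILE.provenance_marker in types
        cc_node = URIRef(NS["cooccurrence"] + "CID1_CID2")
        assert (cc_node, RDF.type,
                PROFILE.association_classes["compound-compound"]) in g

    def test_score_literal_is_integer_typed(self):
        corpus = [make_record(1, {C(1), D(1)}), make_record(2, {C(1)})]
        g = serialize_cooccurrences(_lists(corpus), PROFILE, NS).graphs["cooccurrence"]
        for _, _, o in g.triples((None, PROFILE.score_predicate, None)):
            assert o.datatype == XSD.integer and int(o) >= 0

    def test_empty_lists_give_no_triples(self):
        assert serialize_cooccurrences({}, PROFILE, NS).triple_count() == 0

    def test_missing_pair_class_named_in_error(self):
        profile = PROFILE.with_overrides(association_classes={})
        corpus = [make_record(1, {C(1), D(1)})]
        with pytest.raises(SerializationError, match="compound-disease"):
            serialize_cooccurrences(_lists(corpus), profile, NS)

    def test_cooccurrence_subjects_parse_back(self):
        corpus = [make_record(1, {C(1), G("hoxa@"), D(2)})]
        g = serialize_cooccurrences(_lists(corpus), PROFILE, NS).graphs["cooccurrence"]
        for node in set(g.subjects()):
            subject, obj = parse_cooccurrence_uri(str(node), NS)
            assert (node, RDF.subject, None) in g
            assert subject != obj


class TestReferenceTriples:
    def test_mention_triples_use_text_mining_predicate(self):
        rec = make_record(1, {C(3715), D(8173)})
        g = serialize_references([rec], PROFILE, NS).graphs["reference"]
        node = URIRef(NS["reference"] + "PMID1")
        mentions = set(g.objects(node, PROFILE.mention_predicate))
        assert mentions == {URIRef(NS["compound"] + "CID3715"),
                            URIRef(NS["disease"] + "DZID8173")}

    def test_grantless_agency_is_linked_directly(self):
        rec = make_record(1, set(), grants=(Grant(None, "NIH"), Grant("R01", "NSF")))
        bundle = serialize_references([rec], PROFILE, NS)
        ref_g = bundle.graphs["reference"]
        node = URIRef(NS["reference"] + "PMID1")
        direct = list(ref_g.objects(node, PROFILE.agency_predicate))
        assert direct == [URIRef(NS["organization"] + "NIH")]
        grants = list(ref_g.objects(node, PROFILE.grant_link_predicate))
        assert len(grants) == 1  # only the numbered grant gets a grant node
        assert (grants[0], PROFILE.agency_predicate,
                URIRef(NS["organization"] + "NSF")) in bundle.graphs["grant"]

    def test_zero_mentions_still_emits_metadata(self):
        rec = make_record(1, set())
        g = serialize_references([rec], PROFILE, NS).graphs["reference"]
        node = URIRef(NS["reference"] + "PMID1")
        assert list(g.objects(node, PROFILE.mention_predicate)) == []
        assert g.value(node, PROFILE.title_predicate) is not None
        assert g.value(node, PROFILE.date_predicate) is not None

    def test_review_and_pmc_markers(self):
        rec = make_record(1, set(), is_review=True, pmc_id="PMC42")
        g = serialize_references([rec], PROFILE, NS).graphs["reference"]
        node = URIRef(NS["reference"] + "PMID1")
        assert (node, RDF.type, PROFILE.review_class) in g
        assert str(g.value(node, PROFILE.pmc_predicate)) == "PMC42"


class TestEntityTriples:
    def test_labels_gene_records_and_roles(self):
        ann = EntityAnnotations(
            disease_labels={"8173": "Inflammation"},
            gene_records={"brca1": (GeneRecord(672, 9606, "BRCA1 protein"),)},
            compound_roles={"3715": frozenset({"FDAApprovedDrugs"})},
        )
        bundle = serialize_entities(ann, PROFILE, NS)
        assert str(bundle.graphs["disease"].value(
            URIRef(NS["disease"] + "DZID8173"), PROFILE.label_predicate)) == "Inflammation"
        gid = URIRef(NS["gene"] + "GID672")
        g = bundle.graphs["gene"]
        assert g.value(gid, PROFILE.gene_symbol_predicate) == URIRef(NS["gene"] + "brca1")
        assert g.value(gid, PROFILE.organism_predicate) == URIRef(NS["taxonomy"] + "TAXID9606")
        assert (URIRef(NS["compound"] + "CID3715"), PROFILE.role_predicate,
                URIRef(NS["vocab"] + "FDAApprovedDrugs")) in bundle.graphs["compound"]


class TestBundleIO:
    @pytest.mark.parametrize("fmt", ["turtle", "ntriples"])
    def test_write_read_round_trip(self, tmp_path, one_corpus, fmt):
        _, _, bundle, _ = one_corpus
        write_bundle(bundle, tmp_path / fmt, format=fmt)
        back = read_bundle(tmp_path / fmt)
        assert back.triple_set() == bundle.triple_set()
        for name, g in bundle.graphs.items():
            if len(g):
                assert set(back.graphs[name]) == set(g)

    def test_one_subdirectory_per_nonempty_subdomain(self, tmp_path):
        corpus = [make_record(1, {C(1), D(1)})]
        bundle = serialize_cooccurrences(_lists(corpus), PROFILE, NS)
        bundle.merge(serialize_references(corpus, PROFILE, NS))
        write_bundle(bundle, tmp_path, format="ntriples")
        dirs = sorted(p.name for p in tmp_path.iterdir() if p.is_dir())
        assert dirs == ["cooccurrence", "journal", "reference"]

    def test_ntriples_canonical_and_deterministic(self, tmp_path, one_corpus):
        records, annotations, _, _ = one_corpus
        paths = []
        for run in ("a", "b"):
            bundle = build_bundle(records, annotations, _lists(records))
            write_bundle(bundle, tmp_path / run, format="ntriples")
            paths.append(sorted((tmp_path / run).rglob("*.nt")))
        for p1, p2 in zip(*paths):
            assert p1.read_bytes() == p2.read_bytes()
            lines = p1.read_text().splitlines()
            assert lines == sorted(lines)
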
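"""Every query operation is checked against its brute-force record-scan
oracle on seeded synthetic corpora, plus targeted constructed scenarios
(planted implicit associations, filter semantics, empty anchors)."""

import pytest

from coocrdf import (
    EntityAnnotations,
    EntityKind,
    EntityRef,
    GeneRecord,
)

import oracles
from conftest import build_store, make_record

C, D, G = EntityRef.compound, EntityRef.disease, EntityRef.gene


class TestOracleEquivalence:
    """Pure record scans vs. the SPARQL path, over 20 seeded corpora."""

    def test_top_neighbors(self, seeded_corpora):
        for records, _, _, store in seeded_corpora:
            for anchor in (C(1), C(10), D(1), G("hoxa@")):
                for kind in EntityKind:
                    got = [(r.neighbor, r.serialized_score)
                           for r in store.top_neighbors(anchor, kind, 25)]
                    assert got == oracles.top_neighbors(records, anchor, kind, 25)

    def test_corefs(self, seeded_corpora):
        for records, _, _, store in seeded_corpora:
            for a, b in ((C(1), D(1)), (C(2), G("il-6"))):
                for flags in ({}, {"review_only": True}, {"pmc_only": True},
                              {"review_only": True, "pmc_only": True}):
                    got = [(r.date, r.journal, r.title, r.pmc_id)
                           for r in store.corefs(a, b, 10, **flags)]
                    assert got == oracles.corefs(records, a, b, 10, **flags)

    def test_implicit_diseases(self, seeded_corpora):
        for records, _, _, store in seeded_corpora:
            got = [(r.disease, r.serialized_score, r.directly_comentioned)
                   for r in store.implicit_diseases(C(1), 10)]
            assert got == oracles.implicit_diseases(records, C(1), 10)

    def test_chemicals_for_genes(self, seeded_corpora):
        for records, annotations, _, store in seeded_corpora:
            genes = [r.neighbor for r in store.top_neighbors(C(1), "gene", 3)]
            if not genes:
                continue
            for role in (None, "FDAApprovedDrugs"):
                got = [(r.compound, r.per_gene_scores, r.total_score)
                       for r in store.chemicals_for_genes(genes, role, 10)]
                assert got == oracles.chemicals_for_genes(
                    records, annotations, genes, role, 10)

    def test_count_refs_mentioning_all(self, seeded_corpora):
        for records, annotations, _, store in seeded_corpora:
            genes = [r.neighbor for r in store.top_neighbors(C(1), "gene", 2)]
            if not genes:
                continue
            got = [(r.compound, r.n_refs)
                   for r in store.count_refs_mentioning_all(genes)]
            assert got == oracles.count_refs_mentioning_all(
                records, annotations, genes)

    def test_genes_for_diseases(self, seeded_corpora):
        for records, annotations, _, store in seeded_corpora:
            for human_only in (True, False):
                got = [(r.symbol, r.preferred_name, r.score_1, r.score_2, r.total_score)
                       for r in store.genes_for_diseases(D(1), D(2), 20, human_only)]
                assert got == oracles.genes_for_diseases(
                    records, annotations, D(1), D(2), 20, human_only)


class TestReadOnly:
    def test_store_size_unchanged_by_queries(self, one_corpus):
        _, _, _, store = one_corpus
        before = len(store)
        store.top_neighbors(C(1), "disease", 25)
        store.corefs(C(1), D(1), 10)
        store.implicit_diseases(C(1), 10)
        store.genes_for_diseases(D(1), D(2), 20)
        assert len(store) == before


class TestTopNeighbors:
    def test_below_limit_returns_all(self):
        records = [make_record(i, {C(1), D(i)}) for i in (1, 2, 3)]
        _, store = build_store(records)
        assert len(store.top_neighbors(C(1), "disease", 25)) == 3

    def test_limit_truncates_to_25(self):
        records = [make_record(i, {C(1), D(i % 40 + 1)}) for i in range(1, 90)]
        _, store = build_store(records)
        assert len(store.top_neighbors(C(1), "disease")) == 25

    def test_unknown_anchor_gives_empty_result(self, one_corpus):
        _, _, _, store = one_corpus
        assert store.top_neighbors(C(99999), "disease", 25) == []

    def test_reproduces_serialized_neighbor_list(self, one_corpus):
        from coocrdf import build_neighbor_lists
        records, _, _, store = one_corpus
        lists = build_neighbor_lists(records)
        nl = lists[(C(1), EntityKind.DISEASE)]
        got = store.top_neighbors(C(1), "disease", limit=len(nl.entries))
        assert [(r.neighbor, r.serialized_score) for r in got] == \
            [(e.object, e.serialized_score) for e in nl.entries]


class TestCorefs:
    def test_disjoint_pair_is_empty(self):
        records = [make_record(1, {C(1)}), make_record(2, {D(1)})]
        _, store = build_store(records)
        assert store.corefs(C(1), D(1)) == []

    def test_dates_non_increasing_and_limited(self, seeded_corpora):
        for records, _, _, store in seeded_corpora[:5]:
            rows = store.corefs(C(1), D(1), 10)
            dates = [r.date for r in rows]
            assert dates == sorted(dates, reverse=True)
            assert len(rows) <= 10


class TestImplicitDiseases:
    def _planted(self):
        # disease D(50) co-occurs with gene G but never with chemical C(9);
        # G is C(9)'s only (hence top) gene neighbor
        records = [
            make_record(1, {C(9), G("tnf")}),
            make_record(2, {C(9), G("tnf")}),
            make_record(3, {G("tnf"), D(50)}),
            make_record(4, {G("tnf"), D(7), C(9)}),
            make_record(5, {D(7), C(1)}),
        ]
        return build_store(records)

    def test_implicit_association_flagged_false(self):
        _, store = self._planted()
        rows = {r.disease: r.directly_comentioned
                for r in store.implicit_diseases(C(9), 10)}
        assert rows[D(50)] is False   # reachable only through the gene
        assert rows[D(7)] is True     # also directly co-mentioned

    def test_chemical_without_gene_neighbors_is_empty(self):
        records = [make_record(1, {C(3), D(1)}), make_record(2, {C(3)})]
        _, store = build_store(records)
        assert store.implicit_diseases(C(3), 10) == []


class TestChemicalsForGenes:
    def test_single_gene_reduces_to_top_neighbors(self, one_corpus):
        _, _, _, store = one_corpus
        gene = G("hoxa@")
        hits = store.chemicals_for_genes([gene], limit=10)
        top = store.top_neighbors(gene, "compound", 10)
        assert [(h.compound, h.total_score) for h in hits] == \
            [(r.neighbor, r.serialized_score) for r in top]

    def test_intersection_semantics(self):
        records = [
            make_record(1, {G("a1"), C(1)}),
            make_record(2, {G("b1"), C(1)}),
            make_record(3, {G("a1"), C(2)}),  # C(2) misses gene b1's list
            make_record(4, {G("a1"), G("b1")}),
        ]
        _, store = build_store(records)
        hits = store.chemicals_for_genes([G("a1"), G("b1")], limit=10)
        assert [h.compound for h in hits] == [C(1)]

    def test_role_filter(self):
        ann = EntityAnnotations(compound_roles={"1": frozenset({"FDAApprovedDrugs"})})
        records = [make_record(1, {G("a1"), C(1), C(2)})]
        _, store = build_store(records, ann)
        hits = store.chemicals_for_genes([G("a1")], role="FDAApprovedDrugs")
        assert [h.compound for h in hits] == [C(1)]


class TestCountRefs:
    def test_planted_quadruple_counted_exactly(self):
        genes = (G("a1"), G("b1"), G("c1"))
        quad = {C(5), *genes}
        records = [make_record(i, quad) for i in (1, 2, 3, 4)]
        records += [make_record(5, {C(5), G("a1")}), make_record(6, {C(6), *genes})]
        _, store = build_store(records)
        counts = {r.compound: r.n_refs
                  for r in store.count_refs_mentioning_all(list(genes))}
        assert counts[C(5)] == 4

    def test_compound_without_joint_reference_omitted(self):
        # C(2) is in both gene lists but never in one record with both genes
        records = [
            make_record(1, {G("a1"), C(2)}),
            make_record(2, {G("b1"), C(2)}),
            make_record(3, {G("a1"), G("b1"), C(1)}),
        ]
        _, store = build_store(records)
        compounds = [r.compound for r in
                     store.count_refs_mentioning_all([G("a1"), G("b1")])]
        assert C(2) not in compounds and C(1) in compounds


class TestGenesForDiseases:
    def test_gene_absent_from_second_disease_excluded(self):
        records = [
            make_record(1, {D(1), G("a1")}),
            make_record(2, {D(2), G("a1")}),
            make_record(3, {D(1), G("b1")}),  # b1 never with D(2)
        ]
        ann = EntityAnnotations(gene_records={
            "a1": (GeneRecord(1, 9606, "A1 protein"),),
            "b1": (GeneRecord(2, 9606, "B1 protein"),),
        })
        _, store = build_store(records, ann)
        rows = store.genes_for_diseases(D(1), D(2), 20)
        assert [r.symbol for r in rows] == ["a1"]

    def test_human_only_drops_symbols_without_human_record(self):
        records = [
            make_record(1, {D(1), G("a1"), G("b1")}),
            make_record(2, {D(2), G("a1"), G("b1")}),
        ]
        ann = EntityAnnotations(gene_records={
            "a1": (GeneRecord(1, 9606, "A1 protein"),),
            "b1": (GeneRecord(2, 10090, "B1 protein"),),  # mouse only
        })
        _, store = build_store(records, ann)
        human = store.genes_for_diseases(D(1), D(2), 20, human_only=True)
        assert [r.symbol for r in human] == ["a1"]
        all_species = store.genes_for_diseases(D(1), D(2), 20, human_only=False)
        assert {r.symbol for r in all_species} == {"a1", "b1"}
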
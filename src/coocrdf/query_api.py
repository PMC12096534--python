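"""The five literature-mining use cases as parametrized SPARQL operations.

Each operation substitutes its parameters into a SPARQL template shipped
as a text asset (``coocrdf/queries/*.rq``) and executes it against an
in-memory store holding the serialized graph -- the RDF model itself is
what answers the question; no operation falls back to scanning the input
records.

Use cases:

1. ``top_neighbors`` -- neighbors of one kind for an anchor entity,
   score-descending (the "knowledge panel" retrieval; default limit 25).
2. ``corefs`` -- most recent references co-mentioning two entities, with
   review-only / PMC-only filters (default limit 10).
3. ``implicit_diseases`` -- diseases reached through the anchor
   chemical's top co-mentioned gene, flagged by whether a direct
   chemical-disease association also exists.
4. ``chemicals_for_genes`` + ``count_refs_mentioning_all`` -- compounds
   co-mentioned with several genes (sum-of-scores ranking, optional role
   filter), and how many single references mention a compound together
   with *all* the genes.
5. ``genes_for_diseases`` -- genes shared by the top neighbor lists of
   two diseases (comorbidity candidates), names resolved through
   species-specific gene records.

All operations are read-only and return empty sequences for unknown
anchors, matching SPARQL's open-world behavior.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from string import Template
from typing import Sequence

from rdflib import Graph, URIRef

from .corpus_model import EntityKind, EntityRef
from .rdf_serializer import GraphBundle, PredicateProfile
from .scoring import pair_class
from .uri_minting import NamespaceTable, mint_entity_uri, parse_entity_uri


@dataclass(frozen=True)
class NeighborRow:
    neighbor: EntityRef
    serialized_score: int
    label: str | None = None


@dataclass(frozen=True)
class ReferenceRow:
    date: dt.date
    journal: str
    title: str
    pmc_id: str | None = None


@dataclass(frozen=True)
class ImplicitDiseaseRow:
    disease: EntityRef
    serialized_score: int
    directly_comentioned: bool
    label: str | None = None


@dataclass(frozen=True)
class CompoundHitRow:
    compound: EntityRef
    per_gene_scores: tuple[int, ...]
    total_score: int
    label: str | None = None


@dataclass(frozen=True)
class CompoundRefCount:
    compound: EntityRef
    n_refs: int


@dataclass(frozen=True)
class GeneComorbidityRow:
    symbol: str
    preferred_name: str | None
    score_1: int
    score_2: int
    total_score: int


@lru_cache(maxsize=None)
def _template(name: str) -> Template:
    text = resources.files("coocrdf").joinpath("queries", f"{name}.rq").read_text("utf-8")
    return Template(text)


def _iri(e: EntityRef, ns: NamespaceTable) -> str:
    return f"<{mint_entity_uri(e, ns)}>"


class CooccurrenceStore:
    """An in-memory SPARQL-capable store over a serialized graph bundle."""

    def __init__(self, graph: Graph, ns: NamespaceTable | None = None,
                 profile: PredicateProfile | None = None) -> None:
        self.graph = graph
        self.ns = ns or NamespaceTable()
        self.profile = profile or PredicateProfile.default(self.ns)

    @classmethod
    def from_bundle(cls, bundle: GraphBundle,
                    profile: PredicateProfile | None = None) -> "CooccurrenceStore":
        return cls(bundle.union(), bundle.ns, profile)

    def __len__(self) -> int:
        return len(self.graph)

    def _run(self, name: str, **subs):
        text = _template(name).substitute(prefixes=self.ns.sparql_prefixes(), **subs)
        return self.graph.query(text)

    def _assoc_class(self, kind_a: EntityKind, kind_b: EntityKind) -> str:
        cls = self.profile.association_classes[pair_class(kind_a, kind_b)]
        return f"<{cls}>"

    # -- use case 1 --------------------------------------------------------

    def top_neighbors(self, anchor: EntityRef, kind: EntityKind | str,
                      limit: int = 25) -> list[NeighborRow]:
        kind = EntityKind(kind)
        rows = self._run(
            "uc1_top_neighbors",
            assoc_class=self._assoc_class(anchor.kind, kind),
            anchor=_iri(anchor, self.ns),
            limit=int(limit),
        )
        out = []
        for row in rows:
            neighbor = parse_entity_uri(str(row.neighbor), self.ns)
            if neighbor.kind is not kind:  # same-kind anchor sharing the class
                continue
            out.append(NeighborRow(
                neighbor=neighbor,
                serialized_score=int(row.score.toPython()),
                label=str(row.label) if row.label is not None else None,
            ))
        return out

    # -- use case 2 --------------------------------------------------------

    def corefs(self, a: EntityRef, b: EntityRef, limit: int = 10,
               review_only: bool = False, pmc_only: bool = False) -> list[ReferenceRow]:
        rows = self._run(
            "uc2_corefs",
            entity_a=_iri(a, self.ns),
            entity_b=_iri(b, self.ns),
            review_clause="  ?ref rdf:type vocab:ReviewArticle .\n" if review_only else "",
            pmc_clause="  FILTER(BOUND(?pmcid))\n" if pmc_only else "",
            limit=int(limit),
        )
        return [
            ReferenceRow(
                date=row.date.toPython(),
                journal=str(row.journal),
                title=str(row.title),
                pmc_id=str(row.pmcid) if row.pmcid is not None else None,
            )
            for row in rows
        ]

    # -- use case 3 --------------------------------------------------------

    def implicit_diseases(self, chemical: EntityRef,
                          n_diseases: int = 10) -> list[ImplicitDiseaseRow]:
        rows = self._run(
            "uc3_implicit_diseases",
            chemical=_iri(chemical, self.ns),
            limit=int(n_diseases),
        )
        return [
            ImplicitDiseaseRow(
                disease=parse_entity_uri(str(row.disease), self.ns),
                serialized_score=int(row.score.toPython()),
                directly_comentioned=bool(row.direct.toPython()),
                label=str(row.label) if row.label is not None else None,
            )
            for row in rows
        ]

    # -- use case 4 --------------------------------------------------------

    def _gene_blocks(self, genes: Sequence[EntityRef]) -> tuple[str, str]:
        blocks = []
        for i, gene in enumerate(genes):
            blocks.append(
                f"  ?co{i} rdf:type sio:SIO_001257 ;\n"
                f"        rdf:subject {_iri(gene, self.ns)} ;\n"
                f"        rdf:object ?compound ;\n"
                f"        sio:SIO_000300 ?s{i} .\n"
            )
        score_vars = " ".join(f"?s{i}" for i in range(len(genes)))
        return "".join(blocks), score_vars

    def _role_clause(self, role: str | None) -> str:
        if role is None:
            return ""
        return f"  ?compound obo:RO_0000087 <{self.ns['vocab'] + role}> .\n"

    def chemicals_for_genes(self, genes: Sequence[EntityRef], role: str | None = None,
                            limit: int | None = 10) -> list[CompoundHitRow]:
        genes = list(genes)
        if not genes:
            raise ValueError("at least one gene is required")
        blocks, score_vars = self._gene_blocks(genes)
        rows = self._run(
            "uc4_chemicals_for_genes",
            gene_blocks=blocks,
            score_vars=score_vars,
            score_sum=" + ".join(f"?s{i}" for i in range(len(genes))),
            role_clause=self._role_clause(role),
            limit_clause=f"LIMIT {int(limit)}" if limit is not None else "",
        )
        out = []
        for row in rows:
            scores = tuple(int(row[f"s{i}"].toPython()) for i in range(len(genes)))
            out.append(CompoundHitRow(
                compound=parse_entity_uri(str(row.compound), self.ns),
                per_gene_scores=scores,
                total_score=int(row.total.toPython()),
                label=str(row.label) if row.label is not None else None,
            ))
        return out

    def count_refs_mentioning_all(self, genes: Sequence[EntityRef],
                                  role: str | None = None) -> list[CompoundRefCount]:
        genes = list(genes)
        if not genes:
            raise ValueError("at least one gene is required")
        blocks, _ = self._gene_blocks(genes)
        ref_lines = "".join(
            f"  ?ref vocab:discussesAsDerivedByTextMining {_iri(g, self.ns)} .\n"
            for g in genes
        )
        rows = self._run(
            "uc4_count_refs",
            gene_blocks=blocks,
            role_clause=self._role_clause(role),
            ref_gene_lines=ref_lines,
        )
        return [
            CompoundRefCount(
                compound=parse_entity_uri(str(row.compound), self.ns),
                n_refs=int(row.nrefs.toPython()),
            )
            for row in rows
        ]

    # -- use case 5 --------------------------------------------------------

    def genes_for_diseases(self, d1: EntityRef, d2: EntityRef,
                           inner_limit: int = 20,
                           human_only: bool = True) -> list[GeneComorbidityRow]:
        if human_only:
            name_clause = (
                "  ?gid bao:BAO_0002870 ?gene .\n"
                "  ?gid up:organism taxonomy:TAXID9606 .\n"
                "  ?gid skos:prefLabel ?name .\n"
            )
        else:
            name_clause = (
                "  OPTIONAL { ?gid bao:BAO_0002870 ?gene . ?gid skos:prefLabel ?name . }\n"
            )
        rows = self._run(
            "uc5_genes_for_diseases",
            disease1=_iri(d1, self.ns),
            disease2=_iri(d2, self.ns),
            inner_limit=int(inner_limit),
            name_clause=name_clause,
        )
        out: list[GeneComorbidityRow] = []
        seen: set[str] = set()
        for row in rows:
            symbol = parse_entity_uri(str(row.gene), self.ns).local_id
            if symbol in seen:  # several gene records can share one symbol
                continue
            seen.add(symbol)
            out.append(GeneComorbidityRow(
                symbol=symbol,
                preferred_name=str(row.name) if row.name is not None else None,
                score_1=int(row.s1.toPython()),
                score_2=int(row.s2.toPython()),
                total_score=int(row.total.toPython()),
            ))
        return out
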
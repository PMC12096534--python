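"""Brute-force record-scan oracles for the query operations.

These recompute every answer directly from the pre-RDF reference records
with nested loops and explicit arithmetic (log10, floor-based rounding),
independently of the scoring/serialization/query path under test.  Tie
order follows the pipeline's documented rule: serialized score descending,
then object IRI ascending (IRIs are minted only to order ties).
"""

from __future__ import annotations

import math
from collections import Counter

from coocrdf.corpus_model import EntityKind, EntityRef
from coocrdf.uri_minting import mint_entity_uri

K_CAP = 1000
SCALE = 100


def serialized(c: int, df_obj: int, n: int) -> int:
    raw = c * math.log10(n / df_obj)
    return int(math.floor(SCALE * raw + 0.5))


def df_map(records) -> Counter:
    df = Counter()
    for rec in records:
        for e in rec.mentions:
            df[e] += 1
    return df


def pair_count(records, a: EntityRef, b: EntityRef) -> int:
    return sum(1 for rec in records if a in rec.mentions and b in rec.mentions)


def neighbor_rows(records, anchor: EntityRef, kind: EntityKind,
                  limit: int | None = None, k_cap: int = K_CAP):
    """(neighbor, serialized score) rows of ``anchor``, tie-ordered."""
    n = len(records)
    df = df_map(records)
    neighbors = set()
    for rec in records:
        if anchor in rec.mentions:
            neighbors |= {e for e in rec.mentions if e.kind is kind and e != anchor}
    rows = [
        (b, serialized(pair_count(records, anchor, b), df[b], n))
        for b in neighbors
    ]
    rows.sort(key=lambda r: (-r[1], mint_entity_uri(r[0])))
    rows = rows[:k_cap]
    return rows if limit is None else rows[:limit]


def top_neighbors(records, anchor, kind, limit):
    return neighbor_rows(records, anchor, kind, limit)


def corefs(records, a, b, limit, review_only=False, pmc_only=False):
    hits = [
        rec for rec in records
        if a in rec.mentions and b in rec.mentions
        and (not review_only or rec.is_review)
        and (not pmc_only or rec.pmc_id is not None)
    ]
    hits.sort(key=lambda r: (-r.date.toordinal(), -r.ref_id))
    return [(r.date, r.journal, r.title, r.pmc_id) for r in hits[:limit]]


def implicit_diseases(records, chemical, n_diseases):
    top_genes = neighbor_rows(records, chemical, EntityKind.GENE, limit=1)
    if not top_genes:
        return []
    gene = top_genes[0][0]
    rows = neighbor_rows(records, gene, EntityKind.DISEASE, limit=n_diseases)
    return [
        (disease, s, pair_count(records, chemical, disease) >= 1)
        for disease, s in rows
    ]


def chemicals_for_genes(records, annotations, genes, role=None, limit=10):
    per_gene = [dict(neighbor_rows(records, g, EntityKind.COMPOUND)) for g in genes]
    common = set(per_gene[0])
    for d in per_gene[1:]:
        common &= set(d)
    if role is not None:
        common = {c for c in common
                  if role in annotations.compound_roles.get(c.local_id, ())}
    rows = [
        (c, tuple(d[c] for d in per_gene), sum(d[c] for d in per_gene))
        for c in common
    ]
    rows.sort(key=lambda r: (-r[2], mint_entity_uri(r[0])))
    return rows if limit is None else rows[:limit]


def count_refs_mentioning_all(records, annotations, genes, role=None):
    candidates = [c for c, _, _ in chemicals_for_genes(
        records, annotations, genes, role, limit=None)]
    rows = []
    for compound in candidates:
        needed = {compound, *genes}
        n = sum(1 for rec in records if needed <= rec.mentions)
        if n > 0:
            rows.append((compound, n))
    rows.sort(key=lambda r: (-r[1], mint_entity_uri(r[0])))
    return rows


def genes_for_diseases(records, annotations, d1, d2, inner_limit=20, human_only=True):
    inner = neighbor_rows(records, d1, EntityKind.GENE, limit=inner_limit)
    d2_scores = dict(neighbor_rows(records, d2, EntityKind.GENE))
    rows = []
    for gene, s1 in inner:
        if gene not in d2_scores:
            continue
        recs = annotations.gene_records.get(gene.local_id, ())
        if human_only:
            human = [r for r in recs if r.taxon_id == 9606]
            if not human:
                continue
            name = human[0].preferred_name
        else:
            name = recs[0].preferred_name if recs else None
        s2 = d2_scores[gene]
        rows.append((gene.local_id, name, s1, s2, s1 + s2))
    rows.sort(key=lambda r: (-r[4], mint_entity_uri(EntityRef.gene(r[0]))))
    return rows
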
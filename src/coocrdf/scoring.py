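"""Co-occurrence counting, TF-IDF-style scoring and neighbor-list building.

For entities A and B co-mentioned in c(A,B) references out of a corpus of
N, the directed raw score defaults to

    S_raw(A -> B) = c(A,B) * log10(N / df(B))

a TF-IDF-variant in which the inverse-document-frequency factor penalizes
ubiquitous neighbors.  The score is directional: S(A->B) discounts by the
document frequency of B only, so S(A->B) != S(B->A) in general.  Scores
are serialized as non-negative integers, round(scale * raw) with
``scale`` defaulting to 100 and ties rounded half away from zero.

For every mentioned entity and every neighbor kind a prioritized neighbor
list is kept, truncated to the top ``k`` (default 1000) entries.  Ordering
is by serialized score descending with object-IRI ascending as the tie
break -- the serialized score is the quantity stored in the graph, so the
in-memory lists and the SPARQL view of the data order identically (the raw
score can disagree with this order only within a rounding tie).

The raw-score formula is pluggable (``raw_score_fn``) so an alternative
co-occurrence statistic can be dropped in without touching the rest of the
pipeline.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .corpus_model import EntityKind, EntityRef, ReferenceRecord
from .uri_minting import mint_entity_uri

RawScoreFn = Callable[[int, int, int], float]


class ScoringError(ValueError):
    """Inconsistent counts or invalid scoring parameters."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ScoringParams:
    """Neighbor cap, serialization scale and score-logarithm base.

    ``k=1000`` and ``scale=100`` are the published constants: up to 1000
    co-occurrence neighbors per neighbor type, and integer scores obtained
    by multiplying the raw score by 100 and rounding.
    """

    k: int = 1000
    scale: int = 100
    log_base: float = 10.0
    tie_break: str = "serialized_desc_then_object_uri_asc"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ScoringError("neighbor cap k must be >= 1")
        if self.scale < 1:
            raise ScoringError("serialization scale must be >= 1")
        if self.log_base <= 0 or self.log_base == 1.0:
            raise ScoringError("log_base must be positive and != 1")

    def raw_score_fn(self) -> RawScoreFn:
        base = self.log_base

        def tfidf(c: int, df_obj: int, n_refs: int) -> float:
            return c * (math.log(n_refs / df_obj) / math.log(base))

        return tfidf


_PAIR_CLASS_ORDER = (EntityKind.COMPOUND, EntityKind.GENE, EntityKind.DISEASE)


def pair_class(kind_a: EntityKind, kind_b: EntityKind) -> str:
    """Unordered kind-pair class, e.g. ``compound-disease``.

    Direction does not change the class: a gene->compound association is
    of the chemical-gene class just like a compound->gene one.
    """
    a, b = sorted((kind_a, kind_b), key=_PAIR_CLASS_ORDER.index)
    return f"{a.value}-{b.value}"


PAIR_CLASSES = tuple(
    pair_class(a, b)
    for i, a in enumerate(_PAIR_CLASS_ORDER)
    for b in _PAIR_CLASS_ORDER[i:]
)


@dataclass(frozen=True)
class CooccurrenceRecord:
    """A directed, scored association from ``subject`` to ``object``."""

    subject: EntityRef
    object: EntityRef
    pair_class: str
    comention_count: int
    raw_score: float
    serialized_score: int

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ScoringError("a co-occurrence record needs two distinct entities")
        if self.comention_count < 1:
            raise ScoringError("records are only emitted for co-mentioned pairs")
        if self.serialized_score < 0:
            raise ScoringError("serialized score must be non-negative")


@dataclass(frozen=True)
class NeighborList:
    """The prioritized, truncated neighbors of one anchor for one kind."""

    anchor: EntityRef
    neighbor_kind: EntityKind
    entries: tuple[CooccurrenceRecord, ...]


def document_frequencies(corpus: Sequence[ReferenceRecord]) -> dict[EntityRef, int]:
    """df(E) = number of references whose mention set contains E."""
    if not corpus:
        raise ScoringError("cannot compute document frequencies on an empty corpus")
    df: Counter[EntityRef] = Counter()
    for rec in corpus:
        df.update(rec.mentions)
    return dict(df)


def comention_counts(corpus: Sequence[ReferenceRecord]
                     ) -> dict[tuple[EntityRef, EntityRef], int]:
    """c(A,B) over unordered pairs; pairs never co-mentioned are absent.

    Keys are (A, B) tuples in canonical (kind, id) order.
    """
    if not corpus:
        raise ScoringError("cannot count co-mentions on an empty corpus")
    counts: Counter[tuple[EntityRef, EntityRef]] = Counter()
    for rec in corpus:
        ments = sorted(rec.mentions, key=lambda e: e.sort_key)
        for i, a in enumerate(ments):
            for b in ments[i + 1:]:
                counts[(a, b)] += 1
    return dict(counts)


def score(subject: EntityRef, obj: EntityRef, c: int, df_obj: int, n_refs: int,
          params: ScoringParams | None = None,
          raw_score_fn: RawScoreFn | None = None) -> tuple[float, int]:
    """Directed score of subject -> obj given counts; returns (raw, serialized)."""
    params = params or ScoringParams()
    if not (1 <= c <= df_obj <= n_refs):
        raise ScoringError(
            f"inconsistent counts for {subject}->{obj}: "
            f"need 1 <= c ({c}) <= df ({df_obj}) <= N ({n_refs})"
        )
    fn = raw_score_fn or params.raw_score_fn()
    raw = fn(c, df_obj, n_refs)
    return raw, round_half_away(params.scale * raw)


def build_neighbor_lists(corpus: Sequence[ReferenceRecord],
                         params: ScoringParams | None = None,
                         raw_score_fn: RawScoreFn | None = None,
                         ) -> dict[tuple[EntityRef, EntityKind], NeighborList]:
    """Score every co-mentioned pair in both directions and truncate.

    The result maps (anchor, neighbor kind) to the anchor's prioritized
    list.  Truncation makes neighborhood membership asymmetric: B may sit
    in A's list while A falls outside B's.
    """
    params = params or ScoringParams()
    if not corpus:
        raise ScoringError("cannot build neighbor lists on an empty corpus")
    n = len(corpus)
    df = document_frequencies(corpus)
    fn = raw_score_fn or params.raw_score_fn()
    grouped: dict[tuple[EntityRef, EntityKind], list[CooccurrenceRecord]] = defaultdict(list)
    for (a, b), c in comention_counts(corpus).items():
        cls = pair_class(a.kind, b.kind)
        for subj, obj in ((a, b), (b, a)):
            raw = fn(c, df[obj], n)
            grouped[(subj, obj.kind)].append(CooccurrenceRecord(
                subject=subj, object=obj, pair_class=cls, comention_count=c,
                raw_score=raw, serialized_score=round_half_away(params.scale * raw),
            ))
    lists: dict[tuple[EntityRef, EntityKind], NeighborList] = {}
    for (anchor, kind), records in grouped.items():
        records.sort(key=lambda r: (-r.serialized_score, mint_entity_uri(r.object)))
        lists[(anchor, kind)] = NeighborList(anchor, kind, tuple(records[: params.k]))
    return lists


def export_scored_pairs(lists: Mapping[tuple[EntityRef, EntityKind], NeighborList],
                        path: str | Path) -> None:
    """Tab-separated export: subject, object, c, raw, serialized."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key in sorted(lists, key=lambda k: (k[0].sort_key, k[1].value)):
            for rec in lists[key].entries:
                fh.write(
                    f"{rec.subject}\t{rec.object}\t{rec.comention_count}\t"
                    f"{rec.raw_score:.6f}\t{rec.serialized_score}\n"
                )
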
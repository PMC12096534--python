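"""Input data model for literature co-occurrence corpora.

A corpus is a sequence of literature references (PMID-like records with
bibliographic metadata) each carrying the *set* of named entities --
compounds, genes/proteins, and diseases -- mentioned in its title or
abstract.  Genes and proteins are deliberately conflated into a single
``gene`` namespace keyed by the lowercased gene symbol, because the two
are used interchangeably in the literature and mentions usually lack
organism information; species resolution lives only in
:class:`EntityAnnotations` (symbol -> species-specific gene records).

Mentions are sets, not multisets: downstream co-occurrence scoring counts
*documents* that co-mention a pair, never token frequency within one
document.

The on-disk dialect is a UTF-8 tab-separated file, one reference per line
(see :func:`write_corpus`), plus a directory of small tab-separated
annotation tables.  A JSON-Lines variant ("structured-text") of the same
record layout is also supported.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class CorpusError(ValueError):
    """A corpus or annotation file violates the documented dialect."""


class EntityKind(str, Enum):
    COMPOUND = "compound"
    GENE = "gene"
    DISEASE = "disease"


_KIND_ORDER = {EntityKind.COMPOUND: 0, EntityKind.GENE: 1, EntityKind.DISEASE: 2}


def canonicalize_gene_symbol(raw: str) -> str:
    """Lowercase a gene symbol (the canonical, species-agnostic form).

    Surrounding whitespace is trimmed; interior characters (spaces,
    parentheses, "@", ...) are preserved -- percent-encoding is a URI-level
    concern, not a symbol-level one.  Idempotent.
    """
    sym = raw.strip()
    if not sym:
        raise ValueError("gene symbol must be non-empty")
    return sym.lower()


@dataclass(frozen=True)
class EntityRef:
    """A typed named entity: a compound CID, disease DZID, or gene symbol.

    Equality is (kind, local_id) equality.  Gene symbols are canonicalized
    (lowercased) at construction; CIDs/DZIDs must parse as positive
    integers.
    """

    kind: EntityKind
    local_id: str

    def __post_init__(self) -> None:
        kind = EntityKind(self.kind)
        object.__setattr__(self, "kind", kind)
        lid = str(self.local_id)
        if kind is EntityKind.GENE:
            lid = canonicalize_gene_symbol(lid)
        else:
            if not lid.isdigit() or int(lid) <= 0:
                raise ValueError(
                    f"{kind.value} identifier must be a positive integer, got {lid!r}"
                )
            lid = str(int(lid))
        object.__setattr__(self, "local_id", lid)

    @classmethod
    def compound(cls, cid: int | str) -> "EntityRef":
        return cls(EntityKind.COMPOUND, str(cid))

    @classmethod
    def gene(cls, symbol: str) -> "EntityRef":
        return cls(EntityKind.GENE, symbol)

    @classmethod
    def disease(cls, dzid: int | str) -> "EntityRef":
        return cls(EntityKind.DISEASE, str(dzid))

    @property
    def sort_key(self) -> tuple[int, str]:
        return (_KIND_ORDER[self.kind], self.local_id)

    def __str__(self) -> str:  # the "kind:id" mention token
        return f"{self.kind.value}:{self.local_id}"


def parse_entity_token(token: str) -> EntityRef:
    """Parse a ``kind:id`` mention token (e.g. ``gene:BRCA2``)."""
    kind, sep, lid = token.partition(":")
    if not sep:
        raise CorpusError(f"mention token {token!r} lacks a 'kind:' tag")
    try:
        ek = EntityKind(kind)
    except ValueError:
        raise CorpusError(f"unknown entity kind {kind!r} in token {token!r}") from None
    try:
        return EntityRef(ek, lid)
    except ValueError as exc:
        raise CorpusError(f"bad mention token {token!r}: {exc}") from None


def complete_date(text: str) -> dt.date:
    """Parse an ISO date, completing year or year-month forms to day 1.

    ``"2014"`` -> 2014-01-01, ``"2014-06"`` -> 2014-06-01.  A full
    calendar date is needed for deterministic recency sorting.
    """
    text = text.strip()
    parts = text.split("-")
    try:
        if len(parts) == 1:
            return dt.date(int(parts[0]), 1, 1)
        if len(parts) == 2:
            return dt.date(int(parts[0]), int(parts[1]), 1)
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise CorpusError(f"bad date {text!r}: {exc}") from None


@dataclass(frozen=True)
class Grant:
    """A funding acknowledgment: an agency, with or without a grant number.

    Articles frequently thank an agency without citing a grant number, so
    ``number`` may be ``None``; the agency name is always required.
    """

    number: str | None
    agency: str

    def __post_init__(self) -> None:
        if not self.agency:
            raise ValueError("a grant acknowledgment must name a funding agency")
        if self.number is not None and not self.number:
            object.__setattr__(self, "number", None)


@dataclass(frozen=True)
class ReferenceRecord:
    """One literature reference: metadata plus its set of mentioned entities."""

    ref_id: int
    title: str
    date: dt.date
    journal: str
    issn: str | None = None
    authors: tuple[str, ...] = ()
    grants: tuple[Grant, ...] = ()
    mesh_headings: tuple[str, ...] = ()
    is_review: bool = False
    pmc_id: str | None = None
    mentions: frozenset[EntityRef] = frozenset()

    def __post_init__(self) -> None:
        if self.ref_id <= 0:
            raise ValueError("ref_id must be a positive integer")
        object.__setattr__(self, "mentions", frozenset(self.mentions))
        object.__setattr__(self, "authors", tuple(self.authors))
        object.__setattr__(self, "grants", tuple(self.grants))
        object.__setattr__(self, "mesh_headings", tuple(self.mesh_headings))
        if self.pmc_id == "":
            object.__setattr__(self, "pmc_id", None)
        if self.issn == "":
            object.__setattr__(self, "issn", None)


@dataclass(frozen=True)
class GeneRecord:
    """A species-specific gene record behind a shared gene symbol."""

    gene_record_id: int
    taxon_id: int
    preferred_name: str

    def __post_init__(self) -> None:
        if self.gene_record_id <= 0 or self.taxon_id <= 0:
            raise ValueError("gene_record_id and taxon_id must be positive")


@dataclass
class EntityAnnotations:
    """Optional per-entity annotation tables.

    ``gene_records`` resolves a (species-agnostic) gene symbol to the
    species-specific gene records carrying that symbol; ``compound_roles``
    holds role tags such as ``FDAApprovedDrugs``.
    """

    disease_labels: dict[str, str] = field(default_factory=dict)
    gene_records: dict[str, tuple[GeneRecord, ...]] = field(default_factory=dict)
    compound_roles: dict[str, frozenset[str]] = field(default_factory=dict)
    compound_labels: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        seen: dict[int, str] = {}
        for symbol, records in self.gene_records.items():
            for rec in records:
                prev = seen.setdefault(rec.gene_record_id, symbol)
                if prev != symbol:
                    raise ValueError(
                        f"gene record {rec.gene_record_id} appears under two "
                        f"symbols: {prev!r} and {symbol!r}"
                    )


# ---------------------------------------------------------------------------
# Corpus dialect: readers and writers
# ---------------------------------------------------------------------------

_COLUMNS = (
    "ref_id date journal issn title is_review pmc_id authors grants mesh mentions"
).split()

_FORMAT_ALIASES = {
    "delimited": "delimited",
    "tsv": "delimited",
    "structured-text": "structured-text",
    "jsonl": "structured-text",
}


def _check_field(value: str, what: str, extra_forbidden: str = "") -> str:
    for ch in "\t\n" + extra_forbidden:
        if ch in value:
            raise CorpusError(f"{what} contains forbidden character {ch!r}: {value!r}")
    return value


def _record_to_row(rec: ReferenceRecord) -> list[str]:
    grants = ";".join(
        f"{g.number or ''}|{_check_field(g.agency, 'agency', ';|')}" for g in rec.grants
    )
    return [
        str(rec.ref_id),
        rec.date.isoformat(),
        _check_field(rec.journal, "journal"),
        rec.issn or "",
        _check_field(rec.title, "title"),
        "1" if rec.is_review else "0",
        rec.pmc_id or "",
        ";".join(_check_field(a, "author", ";") for a in rec.authors),
        grants,
        ";".join(_check_field(m, "MeSH heading", ";") for m in rec.mesh_headings),
        ";".join(_check_field(str(m), "mention", ";") for m in sorted(rec.mentions, key=lambda e: e.sort_key)),
    ]


def _row_to_record(fields: Sequence[str], lineno: int) -> ReferenceRecord:
    if len(fields) != len(_COLUMNS):
        raise CorpusError(
            f"line {lineno}: expected {len(_COLUMNS)} tab-separated fields, got {len(fields)}"
        )
    (ref_id, date, journal, issn, title, is_review, pmc_id, authors, grants, mesh, mentions) = fields
    try:
        rid = int(ref_id)
    except ValueError:
        raise CorpusError(f"line {lineno}: ref_id {ref_id!r} is not an integer") from None
    grant_objs = []
    for item in filter(None, grants.split(";")):
        number, sep, agency = item.partition("|")
        if not sep:
            raise CorpusError(f"line {lineno}: grant entry {item!r} lacks '|'")
        try:
            grant_objs.append(Grant(number or None, agency))
        except ValueError as exc:
            raise CorpusError(f"line {lineno}: {exc}") from None
    try:
        return ReferenceRecord(
            ref_id=rid,
            title=title,
            date=complete_date(date),
            journal=journal,
            issn=issn or None,
            authors=tuple(filter(None, authors.split(";"))),
            grants=tuple(grant_objs),
            mesh_headings=tuple(filter(None, mesh.split(";"))),
            is_review=is_review == "1",
            pmc_id=pmc_id or None,
            mentions=frozenset(parse_entity_token(t) for t in filter(None, mentions.split(";"))),
        )
    except (ValueError, CorpusError) as exc:
        raise CorpusError(f"line {lineno}: {exc}") from None


def write_corpus(records: Iterable[ReferenceRecord], path: str | Path,
                 format: str = "delimited") -> None:
    """Write references in the tab-separated (or JSON-Lines) dialect."""
    fmt = _FORMAT_ALIASES.get(format)
    if fmt is None:
        raise ValueError(f"unknown corpus format {format!r}")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            if fmt == "delimited":
                fh.write("\t".join(_record_to_row(rec)) + "\n")
            else:
                row = dict(zip(_COLUMNS, _record_to_row(rec)))
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")


def read_corpus(path: str | Path, format: str = "delimited",
                annotations: str | Path | None = None,
                ) -> tuple[list[ReferenceRecord], EntityAnnotations]:
    """Read a corpus file; optionally also an annotation directory.

    Duplicate ``ref_id`` values, malformed lines, and unknown entity-kind
    tags raise :class:`CorpusError` naming the offending line.
    """
    fmt = _FORMAT_ALIASES.get(format)
    if fmt is None:
        raise ValueError(f"unknown corpus format {format!r}")
    path = Path(path)
    records: list[ReferenceRecord] = []
    seen: set[int] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if fmt == "delimited":
                rec = _row_to_record(line.split("\t"), lineno)
            else:
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"line {lineno}: bad JSON: {exc}") from None
                rec = _row_to_record([str(obj.get(c, "")) for c in _COLUMNS], lineno)
            if rec.ref_id in seen:
                raise CorpusError(f"line {lineno}: duplicate ref_id {rec.ref_id}")
            seen.add(rec.ref_id)
            records.append(rec)
    ann = read_annotations(annotations) if annotations is not None else EntityAnnotations()
    return records, ann


# ---------------------------------------------------------------------------
# Annotation tables (one small TSV per table)
# ---------------------------------------------------------------------------

def write_annotations(ann: EntityAnnotations, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "disease_labels.tsv").open("w", encoding="utf-8") as fh:
        for dzid, label in sorted(ann.disease_labels.items(), key=lambda kv: int(kv[0])):
            fh.write(f"{dzid}\t{label}\n")
    with (directory / "gene_records.tsv").open("w", encoding="utf-8") as fh:
        for symbol, records in sorted(ann.gene_records.items()):
            for rec in records:
                fh.write(f"{symbol}\t{rec.gene_record_id}\t{rec.taxon_id}\t{rec.preferred_name}\n")
    with (directory / "compound_roles.tsv").open("w", encoding="utf-8") as fh:
        for cid, roles in sorted(ann.compound_roles.items(), key=lambda kv: int(kv[0])):
            for role in sorted(roles):
                fh.write(f"{cid}\t{role}\n")
    with (directory / "compound_labels.tsv").open("w", encoding="utf-8") as fh:
        for cid, label in sorted(ann.compound_labels.items(), key=lambda kv: int(kv[0])):
            fh.write(f"{cid}\t{label}\n")


def read_annotations(directory: str | Path) -> EntityAnnotations:
    directory = Path(directory)
    ann = EntityAnnotations()
    p = directory / "disease_labels.tsv"
    if p.exists():
        for lineno, line in enumerate(p.open(encoding="utf-8"), 1):
            if not line.strip():
                continue
            try:
                dzid, label = line.rstrip("\n").split("\t")
            except ValueError:
                raise CorpusError(f"{p.name} line {lineno}: expected 2 fields") from None
            ann.disease_labels[str(int(dzid))] = label
    p = directory / "gene_records.tsv"
    if p.exists():
        tmp: dict[str, list[GeneRecord]] = {}
        for lineno, line in enumerate(p.open(encoding="utf-8"), 1):
            if not line.strip():
                continue
            try:
                symbol, gid, taxon, name = line.rstrip("\n").split("\t")
                rec = GeneRecord(int(gid), int(taxon), name)
            except ValueError as exc:
                raise CorpusError(f"{p.name} line {lineno}: {exc}") from None
            tmp.setdefault(canonicalize_gene_symbol(symbol), []).append(rec)
        ann.gene_records = {s: tuple(rs) for s, rs in tmp.items()}
    p = directory / "compound_roles.tsv"
    if p.exists():
        tmp2: dict[str, set[str]] = {}
        for lineno, line in enumerate(p.open(encoding="utf-8"), 1):
            if not line.strip():
                continue
            try:
                cid, role = line.rstrip("\n").split("\t")
            except ValueError:
                raise CorpusError(f"{p.name} line {lineno}: expected 2 fields") from None
            tmp2.setdefault(str(int(cid)), set()).add(role)
        ann.compound_roles = {c: frozenset(rs) for c, rs in tmp2.items()}
    p = directory / "compound_labels.tsv"
    if p.exists():
        for lineno, line in enumerate(p.open(encoding="utf-8"), 1):
            if not line.strip():
                continue
            try:
                cid, label = line.rstrip("\n").split("\t")
            except ValueError:
                raise CorpusError(f"{p.name} line {lineno}: expected 2 fields") from None
            ann.compound_labels[str(int(cid))] = label
    ann.validate()
    return ann
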
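"""URI construction and parsing for all node kinds.

Compounds and diseases get ``CID{n}`` / ``DZID{n}`` local names under the
PubChem-style compound and disease namespaces.  Genes are identified by
their lowercased gene symbol; because symbols may contain characters that
are not IRI-legal (spaces, "@", parentheses, ...), every character outside
the unreserved set (letters, digits) and the five exception characters
``/ - _ : .`` is percent-encoded as UTF-8 octets with uppercase hex
digits, per the IRI rules of RFC 3987.

Co-occurrence (reified association) nodes concatenate the subject and
object tokens with ``_``: ``CID3715_DZID8173``.  Because CID/DZID tokens
contain uppercase letters while encoded gene tokens never do, the leading
token is unambiguous; for two gene tokens the split is taken at the first
``_`` (symbols containing a literal underscore are therefore ambiguous in
co-occurrence node IRIs, see the methods note).
"""

from __future__ import annotations

import re
import string
from typing import Mapping

from .corpus_model import EntityKind, EntityRef


class UriError(ValueError):
    """An IRI cannot be minted or parsed under the documented scheme."""


PUBCHEM = "http://rdf.ncbi.nlm.nih.gov/pubchem/"

#: Prefix table: the thirteen prefixes used in the use-case queries, plus
#: the subdomain bases for reference metadata and co-occurrence nodes and
#: the vocabularies used when serializing (FRAPO, XSD, SHACL).
DEFAULT_NAMESPACES: dict[str, str] = {
    "bao": "http://www.bioassayontology.org/bao#",
    "compound": PUBCHEM + "compound/",
    "dcterms": "http://purl.org/dc/terms/",
    "disease": PUBCHEM + "disease/",
    "gene": PUBCHEM + "gene/",
    "obo": "http://purl.obolibrary.org/obo/",
    "prism": "http://prismstandard.org/namespaces/basic/3.0/",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "sio": "http://semanticscience.org/resource/",
    "skos": "http://www.w3.org/2004/02/skos/core#",
    "taxonomy": PUBCHEM + "taxonomy/",
    "up": "http://purl.uniprot.org/core/",
    "vocab": PUBCHEM + "vocabulary#",
    # subdomain bases beyond the query prefix table
    "reference": PUBCHEM + "reference/",
    "journal": PUBCHEM + "journal/",
    "author": PUBCHEM + "author/",
    "grant": PUBCHEM + "grant/",
    "organization": PUBCHEM + "organization/",
    "cooccurrence": PUBCHEM + "cooccurrence/",
    "frapo": "http://purl.org/cerif/frapo/",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "sh": "http://www.w3.org/ns/shacl#",
}


class NamespaceTable:
    """A prefix -> namespace-IRI mapping with serialization helpers."""

    def __init__(self, namespaces: Mapping[str, str] | None = None) -> None:
        table = dict(DEFAULT_NAMESPACES)
        if namespaces:
            table.update(namespaces)
        for prefix, iri in table.items():
            if not iri.endswith(("/", "#")):
                raise UriError(f"namespace {prefix}: IRI must end with '/' or '#': {iri!r}")
        self._table = table

    def __getitem__(self, prefix: str) -> str:
        return self._table[prefix]

    def items(self):
        return self._table.items()

    def sparql_prefixes(self) -> str:
        return "\n".join(f"PREFIX {p}: <{iri}>" for p, iri in sorted(self._table.items()))

    def turtle_prefixes(self) -> str:
        return "\n".join(f"@prefix {p}: <{iri}> ." for p, iri in sorted(self._table.items()))

    def bind(self, graph) -> None:
        for p, iri in self._table.items():
            graph.bind(p, iri, override=False)


# characters passed through unencoded in gene-symbol IRIs
_SAFE = frozenset(string.ascii_letters + string.digits + "/-_:.")
_HEX = "0123456789ABCDEF"
_HEXDIGITS = frozenset(string.hexdigits)


def percent_encode(text: str) -> str:
    """Percent-encode ``text`` as UTF-8 octets, uppercase hex.

    Letters, digits and the exception characters ``/ - _ : .`` pass
    through unchanged.
    """
    out: list[str] = []
    for ch in text:
        if ch in _SAFE:
            out.append(ch)
        else:
            out.extend(f"%{b >> 4:X}{b & 0xF:X}" for b in ch.encode("utf-8"))
    return "".join(out)


def percent_decode(text: str) -> str:
    """Inverse of :func:`percent_encode`; rejects malformed escapes."""
    out = bytearray()
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "%":
            esc = text[i + 1 : i + 3]
            if len(esc) != 2 or not set(esc) <= _HEXDIGITS:
                raise UriError(f"malformed percent-escape at offset {i} in {text!r}")
            out.append(int(esc, 16))
            i += 3
        else:
            out.extend(ch.encode("utf-8"))
            i += 1
    try:
        return out.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise UriError(f"percent-escapes do not decode as UTF-8 in {text!r}: {exc}") from None


def entity_token(e: EntityRef) -> str:
    """``CID{n}``, ``DZID{n}``, or the percent-encoded gene symbol."""
    if e.kind is EntityKind.COMPOUND:
        return f"CID{e.local_id}"
    if e.kind is EntityKind.DISEASE:
        return f"DZID{e.local_id}"
    return percent_encode(e.local_id)


def mint_entity_uri(e: EntityRef, ns: NamespaceTable | None = None) -> str:
    ns = ns or _DEFAULT_TABLE
    if e.kind is EntityKind.COMPOUND:
        return ns["compound"] + entity_token(e)
    if e.kind is EntityKind.DISEASE:
        return ns["disease"] + entity_token(e)
    return ns["gene"] + entity_token(e)


_ID_TOKEN_RE = re.compile(r"^(CID|DZID)([0-9]+)$")


def _parse_token(token: str) -> EntityRef:
    m = _ID_TOKEN_RE.match(token)
    if m:
        kind = EntityKind.COMPOUND if m.group(1) == "CID" else EntityKind.DISEASE
        return EntityRef(kind, m.group(2))
    symbol = percent_decode(token)
    if not symbol:
        raise UriError("empty gene token")
    if symbol != symbol.lower():
        raise UriError(f"gene token {token!r} contains uppercase characters")
    return EntityRef.gene(symbol)


def parse_entity_uri(iri: str, ns: NamespaceTable | None = None) -> EntityRef:
    """Inverse of :func:`mint_entity_uri`; decodes percent-escapes."""
    ns = ns or _DEFAULT_TABLE
    for prefix, kind in (("compound", EntityKind.COMPOUND),
                         ("disease", EntityKind.DISEASE),
                         ("gene", EntityKind.GENE)):
        base = ns[prefix]
        if iri.startswith(base):
            local = iri[len(base):]
            if kind is EntityKind.GENE:
                symbol = percent_decode(local)
                if not symbol or symbol != symbol.lower():
                    raise UriError(f"not a valid gene IRI: {iri!r}")
                return EntityRef.gene(symbol)
            m = _ID_TOKEN_RE.match(local)
            expected = "CID" if kind is EntityKind.COMPOUND else "DZID"
            if not m or m.group(1) != expected:
                raise UriError(f"malformed {prefix} IRI: {iri!r}")
            return EntityRef(kind, m.group(2))
    raise UriError(f"IRI {iri!r} is not in a known entity namespace")


def mint_cooccurrence_uri(subject: EntityRef, obj: EntityRef,
                          ns: NamespaceTable | None = None) -> str:
    """Directed co-occurrence node IRI: ``{base}{subj_token}_{obj_token}``."""
    ns = ns or _DEFAULT_TABLE
    return ns["cooccurrence"] + entity_token(subject) + "_" + entity_token(obj)


_LEADING_ID_RE = re.compile(r"^(CID[0-9]+|DZID[0-9]+)_")


def parse_cooccurrence_uri(iri: str, ns: NamespaceTable | None = None
                           ) -> tuple[EntityRef, EntityRef]:
    """Inverse of :func:`mint_cooccurrence_uri`.

    The subject token is taken greedily when it is a CID/DZID token
    (those contain uppercase, which encoded gene tokens never do);
    otherwise the split is at the first underscore.
    """
    ns = ns or _DEFAULT_TABLE
    base = ns["cooccurrence"]
    if not iri.startswith(base):
        raise UriError(f"IRI {iri!r} is not in the cooccurrence namespace")
    rest = iri[len(base):]
    m = _LEADING_ID_RE.match(rest)
    if m:
        first, second = m.group(1), rest[m.end():]
    else:
        first, _, second = rest.partition("_")
        if not second and "_" not in rest:
            raise UriError(f"co-occurrence IRI {iri!r} lacks a '_' separator")
    if not second:
        raise UriError(f"co-occurrence IRI {iri!r} lacks an object token")
    try:
        return _parse_token(first), _parse_token(second)
    except UriError as exc:
        raise UriError(f"cannot parse co-occurrence IRI {iri!r}: {exc}") from None


_DEFAULT_TABLE = NamespaceTable()
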
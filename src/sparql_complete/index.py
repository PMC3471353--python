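"""Language-aware term and namespace index.

Ontological terms (properties, individuals, classes) are indexed by their
human-readable labels, keeping the language tag of every label so that one
opaque URI can be looked up in any language it has been labelled in.  Indexes
can be built directly from RDF documents (RDF/XML or Turtle, via rdflib) or
loaded from / saved to a small JSON preload format.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import rdflib
from rdflib import RDF, RDFS, OWL, URIRef, Literal
from rdflib.namespace import SKOS, DC, DCTERMS

log = logging.getLogger(__name__)

KINDS = ("property", "individual", "class")

#: Annotation properties scanned for human-readable names, in order.
DEFAULT_LABEL_PROPERTIES: tuple[URIRef, ...] = (
    RDFS.label,
    SKOS.prefLabel,
    DC.title,
    DCTERMS.title,
)

#: Annotation properties scanned for descriptions / definitions.
DEFAULT_DESCRIPTION_PROPERTIES: tuple[URIRef, ...] = (
    RDFS.comment,
    DC.description,
    DCTERMS.description,
    SKOS.definition,
)

_PROPERTY_TYPES = {
    OWL.ObjectProperty,
    OWL.DatatypeProperty,
    OWL.AnnotationProperty,
    RDF.Property,
}
_CLASS_TYPES = {OWL.Class, RDFS.Class}


class IndexError_(Exception):
    """Raised when a document cannot be indexed or a JSON index is malformed."""


def local_name(uri: str) -> str:
    """Derive a fallback display label from a URI: the part after '#' or the
    last '/'."""
    if "#" in uri:
        tail = uri.rsplit("#", 1)[1]
    else:
        tail = uri.rstrip("/").rsplit("/", 1)[-1]
    return tail or uri


@dataclass
class LabeledTerm:
    """One ontological term: an opaque URI plus its language-tagged labels.

    ``labels`` and ``descriptions`` are sets of ``(text, lang)`` pairs where
    ``lang`` is an xml:lang tag or ``""`` for untagged literals.  ``types``
    records ``rdf:type`` assertions on individuals, used for registry
    matchmaking.
    """

    uri: str
    kind: str
    labels: set[tuple[str, str]] = field(default_factory=set)
    descriptions: set[tuple[str, str]] = field(default_factory=set)
    types: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.uri:
            raise ValueError("term URI must be non-empty")
        if self.kind not in KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")

    def merge(self, other: "LabeledTerm") -> None:
        """Union the other term's annotations into this one (labels extend,
        never replace)."""
        self.labels |= other.labels
        self.descriptions |= other.descriptions
        self.types |= other.types

    def display_labels(self) -> list[tuple[str, str]]:
        """Labels in deterministic order, with the URI local name as fallback
        when the term has none."""
        if self.labels:
            return sorted(self.labels)
        return [(local_name(self.uri), "")]

    def best_description(self, lang: Optional[str] = None) -> str:
        """A description in the requested language if available, else any
        untagged one, else any at all ('' when the term has none)."""
        if not self.descriptions:
            return ""
        ordered = sorted(self.descriptions)
        if lang:
            for text, tag in ordered:
                if tag == lang:
                    return text
        for text, tag in ordered:
            if not tag:
                return text
        return ordered[0][0]


@dataclass
class NamespaceEntry:
    """A known namespace: suggested short prefix, namespace IRI and a
    human-readable name."""

    prefix: str
    namespace_iri: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.namespace_iri:
            raise ValueError("namespace IRI must be non-empty")
        if any(c.isspace() for c in self.prefix) or ":" in self.prefix:
            raise ValueError(f"invalid namespace prefix {self.prefix!r}")


@dataclass
class Match:
    """One lookup hit: the term, the label that matched, and the match grade
    (1 = label prefix, 2 = word prefix, 3 = label substring,
    4 = description substring)."""

    term: LabeledTerm
    label: str
    lang: str
    grade: int


def match_label(label: str, query: str) -> Optional[int]:
    """Grade a single label against a query (case-insensitive); None if no
    match.  An empty query matches everything at grade 1."""
    q = query.casefold()
    lab = label.casefold()
    if lab.startswith(q):
        return 1
    if any(word.startswith(q) for word in lab.split()):
        return 2
    if q in lab:
        return 3
    return None


class TermIndex:
    """Searchable collection of :class:`LabeledTerm` keyed by URI plus an
    ordered namespace table.

    Re-indexing a URI merges annotations, so label-extension ontologies (for
    example a file adding German ``@de`` labels to already-indexed predicates)
    enrich existing terms instead of duplicating them.
    """

    def __init__(
        self,
        label_properties: Sequence[URIRef] = DEFAULT_LABEL_PROPERTIES,
        description_properties: Sequence[URIRef] = DEFAULT_DESCRIPTION_PROPERTIES,
    ) -> None:
        self.terms: dict[str, LabeledTerm] = {}
        self.namespaces: list[NamespaceEntry] = []
        self.label_properties = tuple(label_properties)
        self.description_properties = tuple(description_properties)

    # ------------------------------------------------------------------ build

    def add_term(self, term: LabeledTerm) -> LabeledTerm:
        existing = self.terms.get(term.uri)
        if existing is None:
            self.terms[term.uri] = term
            return term
        existing.merge(term)
        return existing

    def add_namespace(self, entry: NamespaceEntry) -> None:
        for ns in self.namespaces:
            if ns.namespace_iri == entry.namespace_iri and ns.prefix == entry.prefix:
                if entry.display_name and not ns.display_name:
                    ns.display_name = entry.display_name
                return
        self.namespaces.append(entry)

    def index_ontology(self, source, fmt: Optional[str] = None) -> "TermIndex":
        """Parse an RDF document (path, URL string, or file-like) and merge its
        declared properties, individuals and classes into the index.

        Raises :class:`IndexError_` naming the document when it cannot be
        parsed.  An empty document leaves the index unchanged.
        """
        graph = rdflib.Graph()
        formats = [fmt] if fmt else ["turtle", "xml"]
        err: Optional[Exception] = None
        for f in formats:
            try:
                graph.parse(source, format=f)
                err = None
                break
            except Exception as exc:  # rdflib raises many parser types
                err = exc
                graph = rdflib.Graph()
        if err is not None:
            raise IndexError_(f"cannot parse RDF document {source!r}: {err}")

        kinds: dict[str, str] = {}
        types: dict[str, set[str]] = {}
        for s, t in graph.subject_objects(RDF.type):
            if not isinstance(s, URIRef) or not isinstance(t, URIRef):
                continue
            su = str(s)
            if t in _PROPERTY_TYPES:
                kinds[su] = "property"
            elif t in _CLASS_TYPES:
                kinds.setdefault(su, "class")
            elif t == OWL.NamedIndividual:
                kinds.setdefault(su, "individual")
            else:
                # typed by a domain class: a named individual
                kinds.setdefault(su, "individual")
                types.setdefault(su, set()).add(str(t))

        for uri, kind in kinds.items():
            self.add_term(LabeledTerm(uri, kind, types=types.get(uri, set())))

        # Annotation triples attach to declared terms, or merge onto terms
        # already known to the index (label-extension documents declare none).
        for props, attr in (
            (self.label_properties, "labels"),
            (self.description_properties, "descriptions"),
        ):
            for prop in props:
                for s, o in graph.subject_objects(prop):
                    if not isinstance(s, URIRef) or not isinstance(o, Literal):
                        continue
                    term = self.terms.get(str(s))
                    if term is None:
                        continue
                    getattr(term, attr).add((str(o), o.language or ""))
        return self

    # ----------------------------------------------------------------- lookup

    def match_terms(
        self,
        query: str,
        kind: Optional[str] = None,
        lang: Optional[str] = None,
    ) -> list[Match]:
        """Rank terms against a typed query.

        Labels whose non-empty language tag differs from ``lang`` are excluded
        (untagged labels always qualify).  Each URI appears at most once,
        represented by its best-matching label; ordering is by grade, then
        label (casefolded), then URI.
        """
        hits: list[Match] = []
        for uri in sorted(self.terms):
            term = self.terms[uri]
            if kind and term.kind != kind:
                continue
            best: Optional[Match] = None
            for text, tag in sorted(term.display_labels()):
                if lang and tag and tag != lang:
                    continue
                grade = match_label(text, query)
                if grade is None:
                    continue
                if best is None or (grade, text.casefold()) < (best.grade, best.label.casefold()):
                    best = Match(term, text, tag, grade)
            if best is None and query:
                for text, tag in sorted(term.descriptions):
                    if lang and tag and tag != lang:
                        continue
                    if query.casefold() in text.casefold():
                        labels = [
                            (t, g)
                            for t, g in sorted(term.display_labels())
                            if not (lang and g and g != lang)
                        ]
                        if labels:
                            best = Match(term, labels[0][0], labels[0][1], 4)
                        break
            if best is not None:
                hits.append(best)
        hits.sort(key=lambda m: (m.grade, m.label.casefold(), m.term.uri))
        return hits

    def match_namespaces(self, query: str) -> list[NamespaceEntry]:
        """Namespace entries whose prefix, display name or IRI matches the
        query, best grade first."""
        graded: list[tuple[int, str, NamespaceEntry]] = []
        for ns in self.namespaces:
            grades = [
                g
                for g in (
                    match_label(ns.prefix, query) if ns.prefix else None,
                    match_label(ns.display_name, query) if ns.display_name else None,
                    match_label(ns.namespace_iri, query),
                )
                if g is not None
            ]
            if grades:
                graded.append((min(grades), ns.display_name or ns.prefix, ns))
        graded.sort(key=lambda t: (t[0], t[1].casefold(), t[2].namespace_iri))
        return [ns for _, _, ns in graded]

    # ------------------------------------------------------------------- JSON

    def to_json(self) -> str:
        """Serialize to the JSON preload format."""
        doc = {
            "namespaces": [
                {"prefix": ns.prefix, "uri": ns.namespace_iri, "name": ns.display_name}
                for ns in self.namespaces
            ],
            "terms": [
                {
                    "uri": t.uri,
                    "kind": t.kind,
                    "labels": [
                        {"text": text, "lang": lang} for text, lang in sorted(t.labels)
                    ],
                    "descriptions": [
                        {"text": text, "lang": lang}
                        for text, lang in sorted(t.descriptions)
                    ],
                    "types": sorted(t.types),
                }
                for _, t in sorted(self.terms.items())
            ],
        }
        return json.dumps(doc, ensure_ascii=False, indent=2)

    def load_json(self, document: str) -> "TermIndex":
        """Merge a JSON preload document (see :func:`load_json_index`) into
        this index."""
        try:
            doc = json.loads(document)
        except json.JSONDecodeError as exc:
            raise IndexError_(f"invalid JSON index: {exc}") from exc
        if not isinstance(doc, dict):
            raise IndexError_("invalid JSON index: top level must be an object")
        _warn_unknown(doc, {"namespaces", "terms"}, "$")
        for i, ns in enumerate(_expect_list(doc, "namespaces")):
            path = f"namespaces[{i}]"
            _expect_obj(ns, path)
            _warn_unknown(ns, {"prefix", "uri", "name"}, path)
            uri = _expect_str(ns, "uri", path)
            self.add_namespace(
                NamespaceEntry(ns.get("prefix", ""), uri, ns.get("name", ""))
            )
        for i, t in enumerate(_expect_list(doc, "terms")):
            path = f"terms[{i}]"
            _expect_obj(t, path)
            _warn_unknown(t, {"uri", "kind", "labels", "descriptions", "types"}, path)
            uri = _expect_str(t, "uri", path)
            kind = _expect_str(t, "kind", path)
            if kind not in KINDS:
                raise IndexError_(f"{path}.kind: unknown kind {kind!r}")
            term = LabeledTerm(uri, kind)
            for j, lab in enumerate(t.get("labels", [])):
                lp = f"{path}.labels[{j}]"
                _expect_obj(lab, lp)
                term.labels.add((_expect_str(lab, "text", lp), lab.get("lang", "")))
            for j, desc in enumerate(t.get("descriptions", [])):
                dp = f"{path}.descriptions[{j}]"
                _expect_obj(desc, dp)
                term.descriptions.add(
                    (_expect_str(desc, "text", dp), desc.get("lang", ""))
                )
            for ty in t.get("types", []):
                if not isinstance(ty, str):
                    raise IndexError_(f"{path}.types: entries must be strings")
                term.types.add(ty)
            self.add_term(term)
        return self


def _expect_list(doc: dict, key: str) -> list:
    value = doc.get(key, [])
    if not isinstance(value, list):
        raise IndexError_(f"{key}: expected an array")
    return value


def _expect_obj(value, path: str) -> None:
    if not isinstance(value, dict):
        raise IndexError_(f"{path}: expected an object")


def _expect_str(obj: dict, key: str, path: str) -> str:
    value = obj.get(key)
    if not isinstance(value, str) or not value:
        raise IndexError_(f"{path}.{key}: required non-empty string missing")
    return value


def _warn_unknown(obj: dict, known: set[str], path: str) -> None:
    for key in obj:
        if key not in known:
            log.warning("ignoring unknown key %s.%s in JSON index", path, key)


def index_ontology(source, index: Optional[TermIndex] = None, fmt: Optional[str] = None) -> TermIndex:
    """Module-level convenience: index an RDF document into ``index`` (a new
    index when omitted)."""
    index = index if index is not None else TermIndex()
    return index.index_ontology(source, fmt=fmt)


def load_json_index(document: str, index: Optional[TermIndex] = None) -> TermIndex:
    """Load a JSON preload document of namespaces and terms.

    Schema::

        {"namespaces": [{"prefix": str, "uri": str, "name": str}],
         "terms": [{"uri": str, "kind": "property|individual|class",
                    "labels": [{"text": str, "lang": str}],
                    "descriptions": [{"text": str, "lang": str}],
                    "types": [str]}]}

    Unknown keys are ignored with a logged warning; structural violations
    raise :class:`IndexError_` naming the offending path.
    """
    index = index if index is not None else TermIndex()
    return index.load_json(document)


def export_json_index(index: TermIndex) -> str:
    """Inverse of :func:`load_json_index` (identity up to key ordering)."""
    return index.to_json()
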
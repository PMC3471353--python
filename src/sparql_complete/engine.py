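"""Ranked, context-sensitive completion and query rewriting.

Given the query text and cursor, :class:`CompletionEngine` dispatches on the
grammatical position reported by the partial parser, looks candidates up in
the label index (and, for predicates, the service registry), ranks them, and
— when a suggestion is accepted — splices the corresponding token into the
query, substituting the term's opaque URI for the human-readable label that
was typed.

Ranking: registry-highlighted predicates first, then previously declared
variables (in subject/object positions), then index matches by match grade
(label prefix < word prefix < label substring < description substring), ties
broken lexicographically by display label then URI, truncated to a
configurable maximum (default 10).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Callable, Optional

from .index import Match, TermIndex, local_name, match_label
from .parser import PN_LOCAL_RE, CompletionContext, Position, parse_partial
from .registry import Registry, annotate_predicates, propagate_types

log = logging.getLogger(__name__)

DEFAULT_MAX_SUGGESTIONS = 10

_CATEGORIES = ("keyword", "prefix", "variable", "property", "individual", "class")


@dataclass(frozen=True)
class Suggestion:
    """One ranked completion candidate.

    ``insertion`` is the exact token text spliced into the query on
    acceptance; for ontological terms it is the prefixed name when a declared
    prefix covers the URI, else ``<uri>``.
    """

    display: str
    description: str
    insertion: str
    target_uri: str
    category: str
    grade: int = 1
    highlighted: bool = False

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(f"unknown suggestion category {self.category!r}")
        if not self.insertion:
            raise ValueError("insertion text must be non-empty")

    def replace(self, **kw) -> "Suggestion":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "display": self.display,
            "description": self.description,
            "insertion": self.insertion,
            "uri": self.target_uri,
            "category": self.category,
            "highlighted": self.highlighted,
        }


def term_insertion(uri: str, prefixes: dict[str, str]) -> str:
    """Render a term URI as a token: ``prefix:local`` when a declared prefix
    covers it conservatively, else ``<uri>``.

    Compaction requires the namespace to end in ``/`` or ``#`` and the
    remainder to be a plain PN_LOCAL, so identifier schemes that embed a
    colon in the URI tail (e.g. LSRN-style record URIs) stay in full IRI
    form.  Longest matching namespace wins; ties broken by prefix name.
    """
    best: Optional[tuple[int, str]] = None
    for pfx in sorted(prefixes):
        ns = prefixes[pfx]
        if not ns or not uri.startswith(ns) or not ns.endswith(("/", "#")):
            continue
        local = uri[len(ns):]
        if not PN_LOCAL_RE.match(local):
            continue
        if best is None or len(ns) > best[0]:
            best = (len(ns), f"{pfx}:{local}")
    return best[1] if best else f"<{uri}>"


Fetcher = Callable[[str], tuple[str, Optional[str]]]
"""Maps an IRI to ``(document_text, rdf_format_or_None)``; raising skips the
document with a logged warning."""


class CompletionEngine:
    """Stateful completion session: a term index, an optional service
    registry, and an optional document fetcher for FROM-clause ontologies
    (each FROM IRI fetched at most once per session)."""

    def __init__(
        self,
        index: Optional[TermIndex] = None,
        registry: Optional[Registry] = None,
        fetcher: Optional[Fetcher] = None,
        max_suggestions: int = DEFAULT_MAX_SUGGESTIONS,
        lang: Optional[str] = None,
    ) -> None:
        if max_suggestions < 1:
            raise ValueError("max_suggestions must be >= 1")
        self.index = index if index is not None else TermIndex()
        self.registry = registry
        self.fetcher = fetcher
        self.max_suggestions = max_suggestions
        self.lang = lang
        self._fetched: set[str] = set()

    # ----------------------------------------------------------- FROM clauses

    def resolve_from_clauses(self, context: CompletionContext) -> TermIndex:
        """Fetch and index every not-yet-seen FROM IRI; failures are logged
        and skipped, never surfaced to the completion call."""
        if self.fetcher is None:
            return self.index
        for iri in context.from_iris:
            if iri in self._fetched:
                continue
            self._fetched.add(iri)
            try:
                document, fmt = self.fetcher(iri)
            except Exception as exc:
                log.warning("could not fetch FROM document %s: %s", iri, exc)
                continue
            try:
                import io

                self.index.index_ontology(io.StringIO(document), fmt=fmt)
            except Exception as exc:
                log.warning("could not index FROM document %s: %s", iri, exc)
        return self.index

    # ------------------------------------------------------------ suggestions

    def suggest(self, text: str, cursor: Optional[int] = None) -> list[Suggestion]:
        """Ranked suggestions for the token being typed at ``cursor``
        (default: end of text).  Parse errors propagate with their offset."""
        context = parse_partial(text, cursor)
        self.resolve_from_clauses(context)
        q = context.current_token

        if context.position is Position.KEYWORD:
            out = self._keywords(context, q)
        elif context.position is Position.PREFIX_NAME:
            out = self._prefix_declarations(q)
        elif context.position in (Position.PREFIX_IRI, Position.FROM_IRI):
            out = self._namespace_iris(q)
        elif context.position is Position.SELECT_VAR:
            out = self._variables(context, q) + self._keywords(context, q)
        elif context.position is Position.PREDICATE:
            out = self._predicates(context, q)
        else:  # SUBJECT or OBJECT
            out = self._terms_at_node(context, q)
        return out[: self.max_suggestions]

    # -- per-position candidate builders

    def _keywords(self, context: CompletionContext, q: str) -> list[Suggestion]:
        out = []
        for kw in context.keyword_candidates:
            if kw.casefold().startswith(q.casefold()):
                out.append(
                    Suggestion(
                        display=kw,
                        description="",
                        insertion=kw,
                        target_uri="",
                        category="keyword",
                    )
                )
        return out

    def _prefix_declarations(self, q: str) -> list[Suggestion]:
        """After ``PREFIX``: suggest whole declarations (name + IRI) from the
        known namespace table."""
        query = q[:-1] if q.endswith(":") else q
        out = []
        for ns in self.index.match_namespaces(query):
            pfx = ns.prefix or local_name(ns.namespace_iri)
            out.append(
                Suggestion(
                    display=ns.display_name or pfx,
                    description=ns.namespace_iri,
                    insertion=f"{pfx}: <{ns.namespace_iri}>",
                    target_uri=ns.namespace_iri,
                    category="prefix",
                )
            )
        return out

    def _namespace_iris(self, q: str) -> list[Suggestion]:
        out = []
        for ns in self.index.match_namespaces(q.lstrip("<")):
            out.append(
                Suggestion(
                    display=ns.display_name or ns.prefix or ns.namespace_iri,
                    description=ns.namespace_iri,
                    insertion=f"<{ns.namespace_iri}>",
                    target_uri=ns.namespace_iri,
                    category="prefix",
                )
            )
        return out

    def _variables(self, context: CompletionContext, q: str) -> list[Suggestion]:
        stripped = q.lstrip("?$")
        out = []
        for name in sorted(context.variables):
            if name.casefold().startswith(stripped.casefold()) and (
                q.startswith(("?", "$")) or not q
            ):
                out.append(
                    Suggestion(
                        display=f"?{name}",
                        description="previously declared variable",
                        insertion=f"?{name}",
                        target_uri="",
                        category="variable",
                    )
                )
        return out

    def _term_suggestions(
        self, matches: list[Match], context: CompletionContext, category: str
    ) -> list[Suggestion]:
        out = []
        for m in matches:
            out.append(
                Suggestion(
                    display=m.label,
                    description=m.term.best_description(self.lang),
                    insertion=term_insertion(m.term.uri, context.prefixes),
                    target_uri=m.term.uri,
                    category=category,
                    grade=m.grade,
                )
            )
        return out

    def _terms_at_node(self, context: CompletionContext, q: str) -> list[Suggestion]:
        """Subject/object slots: declared variables first, then named
        individuals; classes when the clause predicate is ``a``."""
        out = self._variables(context, q)
        if q.startswith(("?", "$")):
            return out
        kind = "class" if context.after_rdf_type else "individual"
        matches = self.index.match_terms(q, kind=kind, lang=self.lang)
        out += self._term_suggestions(matches, context, kind)
        return out

    def _predicates(self, context: CompletionContext, q: str) -> list[Suggestion]:
        matches = self.index.match_terms(q, kind="property", lang=self.lang)
        out = self._term_suggestions(matches, context, "property")
        if self.registry is None:
            return self._rank(out)
        # registry-only properties: attached by some service but absent from
        # every loaded ontology; offered under a fallback label, removed again
        # by annotate_predicates when not serviceable for the clause subject
        registry_only = {
            p for p in self.registry.properties() if p not in self.index.terms
        }
        seen = {s.target_uri for s in out}
        for prop in sorted(registry_only - seen):
            grade = match_label(local_name(prop), q)
            if grade is None:
                continue
            out.append(
                Suggestion(
                    display=local_name(prop),
                    description="",
                    insertion=term_insertion(prop, context.prefixes),
                    target_uri=prop,
                    category="property",
                    grade=grade,
                )
            )
        individual_types = {u: t.types for u, t in self.index.terms.items() if t.types}
        assignment = propagate_types(context, self.registry, individual_types)
        out = annotate_predicates(
            out, context, self.registry, assignment, individual_types, registry_only
        )
        return self._rank(out)

    @staticmethod
    def _rank(suggestions: list[Suggestion]) -> list[Suggestion]:
        return sorted(
            suggestions,
            key=lambda s: (
                0 if s.highlighted else 1,
                s.grade,
                s.display.casefold(),
                s.target_uri,
            ),
        )

    # -------------------------------------------------------------- rewriting

    def apply_suggestion(
        self, text: str, cursor: Optional[int], suggestion: Suggestion
    ) -> tuple[str, int]:
        """Splice an accepted suggestion into the query.

        The token being typed (the span ending at the cursor) is replaced by
        the suggestion's insertion text plus one trailing space; the new
        cursor sits after that space.
        """
        if cursor is None:
            cursor = len(text)
        context = parse_partial(text, cursor)
        start = cursor - len(context.current_token)
        inserted = suggestion.insertion + " "
        new_text = text[:start] + inserted + text[cursor:]
        return new_text, start + len(inserted)


def suggest(
    text: str,
    cursor: Optional[int] = None,
    index: Optional[TermIndex] = None,
    registry: Optional[Registry] = None,
    **kw,
) -> list[Suggestion]:
    """One-shot convenience wrapper around :class:`CompletionEngine`."""
    return CompletionEngine(index=index, registry=registry, **kw).suggest(text, cursor)


def apply_suggestion(
    text: str, cursor: Optional[int], suggestion: Suggestion
) -> tuple[str, int]:
    """One-shot convenience wrapper; see
    :meth:`CompletionEngine.apply_suggestion`."""
    return CompletionEngine().apply_suggestion(text, cursor, suggestion)


def suggestions_to_json(suggestions: list[Suggestion]) -> list[dict]:
    """Serializable form shared with the CLI."""
    return [s.to_dict() for s in suggestions]
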
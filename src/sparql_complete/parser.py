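"""Tokenizer and incremental parser for partial SPARQL SELECT queries.

A query under construction is almost never syntactically complete, so the
parser here is built to answer one question: *given the text typed so far and
the cursor position, what grammatical role can be completed here, and what
prefixes, variables and triple patterns already exist?*  It covers the SELECT
subset most query-composition sessions need::

    PREFIX* SELECT [DISTINCT] (var+ | *) FROM* WHERE { BGP }

with OPTIONAL/UNION groups treated as nested basic graph patterns, FILTER
recognized but its parenthesized expression treated as opaque, and ``a``
accepted as the usual shorthand for ``rdf:type``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"

KEYWORDS = {
    "PREFIX",
    "BASE",
    "SELECT",
    "DISTINCT",
    "REDUCED",
    "FROM",
    "WHERE",
    "OPTIONAL",
    "UNION",
    "FILTER",
    "LIMIT",
    "OFFSET",
    "ORDER",
    "BY",
    "ASC",
    "DESC",
    "NAMED",
    "A",
}

PN_LOCAL_RE = re.compile(r"[A-Za-z0-9_][A-Za-z0-9_.\-]*$")

_TOKEN_RE = re.compile(
    r"""
      (?P<iriref><[^<>"{}|^`\\\s]*>?)
    | (?P<variable>[?$][A-Za-z0-9_]*)
    | (?P<literal>"(?:[^"\\\n]|\\.)*"?(?:@[A-Za-z][A-Za-z0-9\-]*|\^\^\S*)?
        |[+-]?[0-9]+(?:\.[0-9]*)?)
    | (?P<word>[A-Za-z_][A-Za-z0-9_.\-]*:[A-Za-z0-9_.\-]*
        |[A-Za-z_][A-Za-z0-9_.\-]*)
    | (?P<punctuation>[{}().;,*]|\])
    """,
    re.VERBOSE,
)


class TokenCategory(str, Enum):
    KEYWORD = "keyword"
    VARIABLE = "variable"
    PREFIXED_NAME = "prefixed_name"
    IRIREF = "iriref"
    LITERAL = "literal"
    PUNCTUATION = "punctuation"
    UNKNOWN = "unknown"


class Position(str, Enum):
    """The grammatical role completable at the cursor."""

    KEYWORD = "KEYWORD"
    PREFIX_NAME = "PREFIX_NAME"
    PREFIX_IRI = "PREFIX_IRI"
    SELECT_VAR = "SELECT_VAR"
    FROM_IRI = "FROM_IRI"
    SUBJECT = "SUBJECT"
    PREDICATE = "PREDICATE"
    OBJECT = "OBJECT"


@dataclass(frozen=True)
class Token:
    text: str
    category: TokenCategory
    start: int
    end: int  # half-open

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


MISSING = None


@dataclass(frozen=True)
class NodeRef:
    """One slot of a triple pattern: a variable, an absolute IRI, or a
    literal."""

    kind: str  # "var" | "iri" | "literal"
    value: str

    def is_var(self) -> bool:
        return self.kind == "var"

    def is_iri(self) -> bool:
        return self.kind == "iri"


@dataclass
class TriplePattern:
    """A (possibly trailing-incomplete) triple pattern; fields fill left to
    right, unfilled ones are None."""

    subject: Optional[NodeRef] = MISSING
    predicate: Optional[NodeRef] = MISSING
    object: Optional[NodeRef] = MISSING

    def is_complete(self) -> bool:
        return self.object is not MISSING

    def variables(self) -> set[str]:
        return {
            n.value
            for n in (self.subject, self.predicate, self.object)
            if n is not None and n.is_var()
        }

    def individuals(self) -> set[str]:
        return {
            n.value
            for n in (self.subject, self.object)
            if n is not None and n.is_iri()
        }


@dataclass
class CompletionContext:
    """Everything the suggestion engine needs to know about the query so far."""

    position: Position
    current_token: str
    cursor: int
    prefixes: dict[str, str] = field(default_factory=dict)
    variables: list[str] = field(default_factory=list)
    triples: list[TriplePattern] = field(default_factory=list)
    from_iris: list[str] = field(default_factory=list)
    keyword_candidates: list[str] = field(default_factory=list)
    after_rdf_type: bool = False  # object position follows an ``a`` predicate

    @property
    def current_clause(self) -> Optional[TriplePattern]:
        return self.triples[-1] if self.triples else None


class ParseError(ValueError):
    """Text before the cursor irrecoverably violates the supported grammar."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


def tokenize(text: str) -> list[Token]:
    """Split query text into tokens.  Total: malformed runs become
    ``unknown`` tokens rather than raising."""
    tokens: list[Token] = []
    pos = 0
    n = len(text)
    while pos < n:
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            # swallow a maximal run of unrecognized non-space characters
            end = pos
            while end < n and not text[end].isspace() and _TOKEN_RE.match(text, end) is None:
                end += 1
            end = max(end, pos + 1)
            tokens.append(Token(text[pos:end], TokenCategory.UNKNOWN, pos, end))
            pos = end
            continue
        kind = m.lastgroup
        tok = m.group(0)
        if kind == "word":
            if ":" in tok:
                category = TokenCategory.PREFIXED_NAME
            elif tok.upper() in KEYWORDS:
                category = TokenCategory.KEYWORD
            else:
                category = TokenCategory.UNKNOWN
        else:
            category = TokenCategory(kind if kind != "word" else "unknown")
        tokens.append(Token(tok, category, m.start(), m.end()))
        pos = m.end()
    return tokens


def _strip_iri(text: str) -> str:
    return text[1:-1] if text.startswith("<") and text.endswith(">") else text.lstrip("<")


class _Done(Exception):
    """Internal: the tokens before the cursor are exhausted; the most recent
    ``at()`` call holds the completable position."""


class _PartialParser:
    """Recursive state machine over the tokens strictly before the cursor
    token."""

    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.i = 0
        self.prefixes: dict[str, str] = {}
        self.variables: list[str] = []
        self.triples: list[TriplePattern] = []
        self.from_iris: list[str] = []
        self.position = Position.KEYWORD
        self.keyword_candidates = ["PREFIX", "SELECT"]
        self.after_rdf_type = False

    # token helpers -----------------------------------------------------

    def peek(self) -> Optional[Token]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def need(self) -> Token:
        """Next token, or stop parsing (cursor reached) if exhausted."""
        tok = self.peek()
        if tok is None:
            raise _Done
        return tok

    def take(self) -> Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def fail(self, message: str, tok: Optional[Token]) -> None:
        offset = tok.start if tok else (self.tokens[-1].end if self.tokens else 0)
        raise ParseError(message, offset)

    def is_kw(self, tok: Optional[Token], *words: str) -> bool:
        return tok is not None and tok.category is TokenCategory.KEYWORD and tok.text.upper() in words

    # node resolution ---------------------------------------------------

    def add_variable(self, name: str) -> None:
        if name and name not in self.variables:
            self.variables.append(name)

    def node(self, tok: Token) -> NodeRef:
        if tok.category is TokenCategory.VARIABLE:
            name = tok.text[1:]
            self.add_variable(name)
            return NodeRef("var", name)
        if tok.category is TokenCategory.IRIREF:
            return NodeRef("iri", _strip_iri(tok.text))
        if tok.category is TokenCategory.PREFIXED_NAME:
            pfx, _, local = tok.text.partition(":")
            if pfx not in self.prefixes:
                self.fail(f"undeclared prefix {pfx!r}", tok)
            return NodeRef("iri", self.prefixes[pfx] + local)
        if tok.category is TokenCategory.LITERAL:
            return NodeRef("literal", tok.text)
        if self.is_kw(tok, "A"):
            return NodeRef("iri", RDF_TYPE)
        self.fail(f"unexpected token {tok.text!r}", tok)
        raise AssertionError  # unreachable

    # grammar -----------------------------------------------------------

    def parse(self) -> None:
        try:
            self.prologue()
        except _Done:
            pass

    def at(self, position: Position, keywords: Optional[list[str]] = None) -> None:
        self.position = position
        self.keyword_candidates = keywords or []

    def prologue(self) -> None:
        while True:
            self.at(Position.KEYWORD, ["PREFIX", "SELECT"])
            tok = self.need()
            if self.is_kw(tok, "PREFIX"):
                self.take()
                self.prefix_decl()
            elif self.is_kw(tok, "SELECT"):
                self.take()
                self.select_clause()
                return
            else:
                self.fail(f"expected PREFIX or SELECT, found {tok.text!r}", tok)

    def prefix_decl(self) -> None:
        self.at(Position.PREFIX_NAME)
        tok = self.need()
        if tok.category is not TokenCategory.PREFIXED_NAME or not tok.text.endswith(":"):
            if tok.category is TokenCategory.PREFIXED_NAME:
                self.fail("prefix declaration name must end with ':'", tok)
            self.fail(f"expected a prefix name, found {tok.text!r}", tok)
        name = self.take().text[:-1]
        self.at(Position.PREFIX_IRI)
        tok = self.need()
        if tok.category is not TokenCategory.IRIREF:
            self.fail(f"expected an IRI after PREFIX {name}:, found {tok.text!r}", tok)
        self.prefixes[name] = _strip_iri(self.take().text)

    def select_clause(self) -> None:
        self.at(Position.SELECT_VAR, ["DISTINCT"])
        tok = self.need()
        if self.is_kw(tok, "DISTINCT", "REDUCED"):
            self.take()
        star = False
        from_seen = False
        while True:
            if from_seen or star:
                self.at(Position.KEYWORD, ["FROM", "WHERE"])
            else:
                self.at(
                    Position.SELECT_VAR,
                    ["FROM", "WHERE"] if (self.variables or star) else ["DISTINCT"],
                )
            tok = self.need()
            if tok.category is TokenCategory.VARIABLE and not from_seen and not star:
                self.add_variable(self.take().text[1:])
            elif tok.category is TokenCategory.PUNCTUATION and tok.text == "*" and not star and not self.variables and not from_seen:
                star = True
                self.take()
            elif self.is_kw(tok, "FROM") and (self.variables or star):
                self.take()
                self.from_clause()
                from_seen = True
            elif self.is_kw(tok, "WHERE") and (self.variables or star):
                self.take()
                self.group_graph_pattern(top=True)
                return
            else:
                self.fail(f"unexpected token {tok.text!r} in SELECT clause", tok)

    def from_clause(self) -> None:
        self.at(Position.FROM_IRI)
        tok = self.need()
        if self.is_kw(tok, "NAMED"):
            self.take()
            self.at(Position.FROM_IRI)
            tok = self.need()
        if tok.category is not TokenCategory.IRIREF:
            self.fail(f"expected an IRI after FROM, found {tok.text!r}", tok)
        self.from_iris.append(_strip_iri(self.take().text))

    def group_graph_pattern(self, top: bool) -> None:
        """WHERE { ... }; called with the WHERE (or OPTIONAL/UNION) consumed."""
        self.at(Position.KEYWORD, ["{"])
        tok = self.need()
        if not (tok.category is TokenCategory.PUNCTUATION and tok.text == "{"):
            self.fail(f"expected '{{', found {tok.text!r}", tok)
        self.take()
        self.bgp()
        tok = self.need()
        if tok.category is TokenCategory.PUNCTUATION and tok.text == "}":
            self.take()
            if top:
                self.solution_modifiers()
        else:
            self.fail(f"expected '}}' to close group, found {tok.text!r}", tok)

    def bgp(self) -> None:
        while True:
            self.at(Position.SUBJECT, ["OPTIONAL", "FILTER"])
            tok = self.need()
            if tok.category is TokenCategory.PUNCTUATION and tok.text == "}":
                return
            if self.is_kw(tok, "OPTIONAL"):
                self.take()
                self.group_graph_pattern(top=False)
                self._maybe_union()
                continue
            if self.is_kw(tok, "FILTER"):
                self.take()
                self._opaque_parens()
                continue
            self.triple_block()
            tok = self.need()
            if tok.category is TokenCategory.PUNCTUATION and tok.text == ".":
                self.take()
                continue
            if tok.category is TokenCategory.PUNCTUATION and tok.text == "}":
                return
            self.fail(f"expected '.', '}}' or end of pattern, found {tok.text!r}", tok)

    def _maybe_union(self) -> None:
        tok = self.peek()
        if self.is_kw(tok, "UNION"):
            self.take()
            self.group_graph_pattern(top=False)
            self._maybe_union()

    def _opaque_parens(self) -> None:
        """Consume a balanced FILTER ( ... ) expression without interpreting
        it; completion inside filters is unsupported."""
        self.at(Position.KEYWORD, ["("])
        tok = self.need()
        if not (tok.category is TokenCategory.PUNCTUATION and tok.text == "("):
            self.fail(f"expected '(' after FILTER, found {tok.text!r}", tok)
        depth = 0
        while True:
            if self.peek() is None:
                # cursor inside the filter: opaque, nothing completable
                self.at(Position.KEYWORD, [])
                raise _Done
            t = self.take()
            if t.category is TokenCategory.PUNCTUATION and t.text == "(":
                depth += 1
            elif t.category is TokenCategory.PUNCTUATION and t.text == ")":
                depth -= 1
                if depth == 0:
                    return

    def triple_block(self) -> None:
        """subject predicate object (';' predicate object)* (',' object)*"""
        subj = self.node(self.take())
        pattern = TriplePattern(subject=subj)
        self.triples.append(pattern)
        while True:
            self.at(Position.PREDICATE)
            self.after_rdf_type = False
            tok = self.need()
            pred = self.node(tok)
            self.take()
            self.triples[-1].predicate = pred
            self.at(Position.OBJECT)
            self.after_rdf_type = pred.is_iri() and pred.value == RDF_TYPE
            tok = self.need()
            self.triples[-1].object = self.node(self.take())
            self.after_rdf_type = False
            self.at(Position.KEYWORD, [])
            while True:
                tok = self.peek()
                if tok is not None and tok.category is TokenCategory.PUNCTUATION and tok.text == ",":
                    self.take()
                    prev = self.triples[-1]
                    self.triples.append(
                        TriplePattern(subject=prev.subject, predicate=prev.predicate)
                    )
                    self.at(Position.OBJECT)
                    self.after_rdf_type = (
                        prev.predicate is not None
                        and prev.predicate.is_iri()
                        and prev.predicate.value == RDF_TYPE
                    )
                    tok = self.need()
                    self.triples[-1].object = self.node(self.take())
                    self.after_rdf_type = False
                    self.at(Position.KEYWORD, [])
                else:
                    break
            tok = self.peek()
            if tok is not None and tok.category is TokenCategory.PUNCTUATION and tok.text == ";":
                self.take()
                prev = self.triples[-1]
                self.triples.append(TriplePattern(subject=prev.subject))
                continue
            return

    def solution_modifiers(self) -> None:
        self.at(Position.KEYWORD, ["LIMIT", "OFFSET"])
        while True:
            tok = self.peek()
            if tok is None:
                return
            if self.is_kw(tok, "LIMIT", "OFFSET"):
                self.take()
                self.at(Position.KEYWORD, [])
                tok = self.need()
                if tok.category is not TokenCategory.LITERAL:
                    self.fail(f"expected a number, found {tok.text!r}", tok)
                self.take()
                self.at(Position.KEYWORD, ["LIMIT", "OFFSET"])
            else:
                self.fail(f"unexpected token {tok.text!r} after query", tok)


_COMPLETABLE = {
    TokenCategory.KEYWORD,
    TokenCategory.VARIABLE,
    TokenCategory.PREFIXED_NAME,
    TokenCategory.UNKNOWN,
    TokenCategory.IRIREF,
    TokenCategory.LITERAL,
}


def parse_partial(text: str, cursor: Optional[int] = None) -> CompletionContext:
    """Parse the text before ``cursor`` and report the completable position.

    The *current token* is the maximal token whose span ends exactly at the
    cursor (an empty token when the cursor follows whitespace or punctuation).
    Text after the cursor never influences the result.
    """
    if cursor is None:
        cursor = len(text)
    if not (0 <= cursor <= len(text)):
        raise ValueError(f"cursor {cursor} out of range for text of length {len(text)}")
    tokens = tokenize(text[:cursor])
    current = ""
    if tokens and tokens[-1].end == cursor and tokens[-1].category in _COMPLETABLE:
        last = tokens[-1]
        # a closed IRIREF is complete, not being typed
        if not (last.category is TokenCategory.IRIREF and last.text.endswith(">")):
            current = last.text
            tokens = tokens[:-1]
    parser = _PartialParser(tokens)
    parser.parse()
    return CompletionContext(
        position=parser.position,
        current_token=current,
        cursor=cursor,
        prefixes=parser.prefixes,
        variables=parser.variables,
        triples=parser.triples,
        from_iris=parser.from_iris,
        keyword_candidates=parser.keyword_candidates,
        after_rdf_type=parser.after_rdf_type,
    )


def graph_neighborhood(
    context: CompletionContext, var: str
) -> tuple[list[TriplePattern], set[str]]:
    """The connected component of the query graph containing ``var``.

    Triple patterns are connected when they share a variable; the returned
    IRI set contains every named individual (IRI in a subject or object slot)
    inside the component.  A variable used in no pattern yields an empty
    component.
    """
    if not any(var in t.variables() for t in context.triples):
        return [], set()
    component: list[TriplePattern] = []
    in_component: set[int] = set()
    vars_seen: set[str] = {var}
    changed = True
    while changed:
        changed = False
        for t in context.triples:
            if id(t) in in_component:
                continue
            if t.variables() & vars_seen:
                component.append(t)
                in_component.add(id(t))
                vars_seen |= t.variables()
                changed = True
    individuals: set[str] = set()
    for t in component:
        individuals |= t.individuals()
    return component, individuals
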
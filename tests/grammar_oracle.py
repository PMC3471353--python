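"""Independent enumeration oracle for the partial parser.

Generates every valid query (as a role-annotated token sequence) of the
supported SELECT subset over a tiny fixed vocabulary, by direct expansion of
the grammar — no use of the parser under test.  From the enumeration a
prefix-continuation map is derived: for each proper prefix of a valid query,
the set of (token, role) pairs that can follow it.

Roles: the parser's position names for completable slots, ``KEYWORD`` for
keywords, ``PUNCT`` for structural punctuation and numbers (not suggested,
so not checked as positions).
"""

from __future__ import annotations

from typing import Iterator

PUNCT = "PUNCT"

PREFIX_DECL = [
    ("PREFIX", "KEYWORD"),
    ("ex:", "PREFIX_NAME"),
    ("<http://e/>", "PREFIX_IRI"),
]
NODES = ["?x", "?y", "<http://e/i>"]
PREDS = ["a", "<http://e/p>"]


def _triple_blocks(max_tail: int = 1) -> Iterator[list[tuple[str, str]]]:
    """subject predicate object with optional ';' / ',' continuations."""
    for s in NODES:
        for p in PREDS:
            for o in NODES:
                base = [(s, "SUBJECT"), (p, "PREDICATE"), (o, "OBJECT")]
                yield base
                if not max_tail:
                    continue
                for p2 in PREDS:
                    for o2 in NODES:
                        yield base + [(";", PUNCT), (p2, "PREDICATE"), (o2, "OBJECT")]
                for o2 in NODES:
                    yield base + [(",", PUNCT), (o2, "OBJECT")]


def _elements(depth: int) -> Iterator[list[list[tuple[str, str]]]]:
    """Sequences of 0..depth BGP elements (triple block, OPTIONAL group,
    FILTER)."""
    yield []
    if depth <= 0:
        return
    simple = [[("?x", "SUBJECT"), ("<http://e/p>", "PREDICATE"), ("?y", "OBJECT")]]
    units: list[list[tuple[str, str]]] = [tb for tb in _triple_blocks()]
    units.append([("OPTIONAL", "KEYWORD"), ("{", PUNCT), ("}", PUNCT)])
    units.append(
        [("OPTIONAL", "KEYWORD"), ("{", PUNCT)] + simple[0] + [("}", PUNCT)]
    )
    units.append([("FILTER", "KEYWORD"), ("(", PUNCT), ("?x", PUNCT), (")", PUNCT)])
    for u in units:
        yield [u]
        if depth >= 2:
            for rest in ([simple[0]], [units[-3]], [units[-1]]):
                yield [u] + rest


def _bgps() -> Iterator[list[tuple[str, str]]]:
    for elems in _elements(depth=2):
        seq: list[tuple[str, str]] = []
        ok = True
        for i, e in enumerate(elems):
            seq.extend(e)
            is_triple = e[0][1] == "SUBJECT"
            if i + 1 < len(elems):
                if is_triple:
                    seq.append((".", PUNCT))
                # groups/filters join without a dot
        if not ok:
            continue
        yield seq
        if elems and elems[-1][0][1] == "SUBJECT":
            yield seq + [(".", PUNCT)]  # trailing dot


def generate_queries(max_prefix_decls: int = 2) -> list[list[tuple[str, str]]]:
    """All valid annotated queries of the subset (bounded repetition)."""
    bodies: list[list[tuple[str, str]]] = []
    for dist in ([], [("DISTINCT", "KEYWORD")]):
        for var_list in (
            [("?x", "SELECT_VAR")],
            [("?x", "SELECT_VAR"), ("?y", "SELECT_VAR")],
            [("?x", "SELECT_VAR"), ("?y", "SELECT_VAR"), ("?z", "SELECT_VAR")],
            [("*", PUNCT)],
        ):
            for frm in ([], [("FROM", "KEYWORD"), ("<http://e/>", "FROM_IRI")]):
                head = [("SELECT", "KEYWORD")] + dist + var_list + frm
                head += [("WHERE", "KEYWORD"), ("{", PUNCT)]
                for bgp in _bgps():
                    body = head + bgp + [("}", PUNCT)]
                    bodies.append(body)
                    bodies.append(body + [("LIMIT", "KEYWORD"), ("1", PUNCT)])
                    bodies.append(body + [("OFFSET", "KEYWORD"), ("2", PUNCT)])
    out = []
    for n in range(max_prefix_decls + 1):
        for body in bodies:
            out.append(PREFIX_DECL * n + body)
    return out


def continuation_map(
    queries: list[list[tuple[str, str]]], max_prefix_len: int = 8
) -> dict[tuple[str, ...], set[tuple[str, str]]]:
    """prefix (as token tuple) -> set of (next token, role)."""
    table: dict[tuple[str, ...], set[tuple[str, str]]] = {}
    for q in queries:
        toks = tuple(t for t, _ in q)
        for i in range(min(len(q), max_prefix_len + 1)):
            table.setdefault(toks[:i], set()).add(q[i])
    return table


def render(prefix: tuple[str, ...]) -> str:
    """Prefix as query text with a trailing space (empty current token)."""
    return " ".join(prefix) + (" " if prefix else "")
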
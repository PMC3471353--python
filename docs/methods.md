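# Methods

## Model

The engine treats query composition as three cooperating components.

**Label index.** Ontological terms are triples' worth of identity (an
absolute URI), a kind (`property`, `individual`, `class`) and two sets of
language-tagged strings: labels and descriptions.  Indexing an RDF document
(via rdflib, Turtle or RDF/XML) classifies every subject by its `rdf:type`
declarations — OWL/RDFS property types map to `property`, `owl:Class`/
`rdfs:Class` to `class`, `owl:NamedIndividual` or any domain-class typing to
`individual` (the domain classes themselves are retained on the term for
registry matchmaking).  Annotation values are harvested from a configurable
property list, by default labels = {`rdfs:label`, `skos:prefLabel`,
`dc:title`, `dcterms:title`} and descriptions = {`rdfs:comment`,
`dc:description`, `dcterms:description`, `skos:definition`}; these defaults
cover the annotation conventions of the vocabularies the package targets, and
both lists are constructor parameters of `TermIndex` for ontologies that use
others.  Re-indexing a URI merges annotation sets, so label-extension
documents (e.g. a file adding `@de` labels to predicates defined elsewhere)
enrich existing terms; a document that only annotates URIs the index has
never seen contributes nothing, since a kind cannot be inferred for them.
A term with no labels falls back to its URI local name so every term stays
findable.

**Partial parser.** A regex scanner splits the text into SPARQL tokens
(total: unrecognized runs become `unknown` tokens), and a recursive-descent
machine consumes the tokens strictly before the cursor.  The *current token*
is the maximal token whose span ends exactly at the cursor; when the tokens
run out, the machine's most recent state names the one grammatical role
completable there (`KEYWORD`, `PREFIX_NAME`, `PREFIX_IRI`, `SELECT_VAR`,
`FROM_IRI`, `SUBJECT`, `PREDICATE`, `OBJECT`) together with the keyword
candidates valid at that point.  Along the way it collects declared prefixes
(expanding prefixed names to absolute IRIs), declared variables in order, the
FROM IRIs, and the triple patterns, where `.` closes a pattern, `;` repeats
the subject and `,` repeats subject and predicate; a pattern fills strictly
left to right and may be trailing-incomplete.  `a` is accepted as the
`rdf:type` shorthand and flags the following object slot so classes rather
than individuals are offered.  Text after the cursor is deliberately ignored:
the reported context is monotone under typing ahead.

**Suggestion engine and registry.** Dispatch on position: keywords from the
parser's candidate set; namespace entries for prefix declarations and FROM
IRIs; declared variables, then individuals (classes after `a`) in
subject/object slots; properties in predicate position.  When a registry is
configured, the clause subject's classes are computed — from its `rdf:type`s
if it is an IRI, or from the propagated type assignment if a variable — and
each predicate suggestion whose URI is attached by a service accepting one of
those classes is highlighted.  Type propagation is a fixpoint: for each
complete pattern `(s, p, ?o)` and record `(T, p, O)` with `O` non-empty and
`T` among the subject's known classes, `O` joins `?o`'s class set;
assignments only grow over a finite class universe, so iteration terminates.
Matchmaking is by exact class IRI — no subsumption reasoning, a deliberate
simplification over systems that reason across OWL class expressions.

## Matching and ranking

Label matching is case-insensitive (Unicode casefold) with four grades:
1 label starts with the query, 2 some whitespace-delimited word of the label
starts with it, 3 the label contains it, 4 only a description contains it.
A language filter excludes labels carrying a *different* non-empty tag;
untagged labels always qualify, since most published ontologies omit
`xml:lang`.  Each URI appears once, represented by its best-graded label.
Ranking tiers: registry-highlighted properties, then declared variables, then
matches by grade; within a tier lexicographic by display label then URI, so
identical inputs always produce identical ordered lists.  Distinct URIs with
identical labels are both shown — equivalence of independently published
terms cannot be assumed — and the list is truncated at `max_suggestions`
(default 10, matching a dropdown-sized display).

URI-to-token rendering is conservative: a term becomes `prefix:local` only
when a declared namespace ending in `/` or `#` covers it and the remainder is
a plain `PN_LOCAL`; identifier schemes that embed a colon in the URI tail
(LSRN-style record URIs such as the KEGG pathway individuals) therefore stay
in full `<...>` form, which also keeps the inserted token unambiguous.

## Synthetic data

`fixtures.walkthrough_fixture()` generates the canonical vocabulary used by
the tests and examples: three SIO predicates with opaque URIs (two with
English descriptions, one without), a second-vocabulary `isEncodedBy` whose
label collides in meaning with "is encoded by", a codes-for predicate under a
placeholder opaque URI labelled only in German, the KEGG caffeine-metabolism
pathway individual labelled in English and German and typed with an
LSRN-style record class, a two-service registry (pathway → genes, gene →
protein), and a namespace table.  All content is fixed text — builds are
byte-identical — and clearly synthetic: description strings and the
codes-for URI are invented, and nothing is fetched from the network.
`fixtures.random_fixture(FixtureSpec(...))` generates seeded pseudo-random
ontologies (counts per kind, label languages, deliberate label collisions)
for the property suites.

What the fixtures do *not* emulate: real SIO/KEGG scale (thousands of terms),
OWL class expressions as service inputs, blank nodes, and noisy annotation
practice (HTML in comments, inconsistent tags).  Passing tests therefore
demonstrate the mechanics — multilingual lookup, URI substitution, collision
handling, matchmaking, propagation — not retrieval quality on full-size
vocabularies.

## Numerical and procedural choices

- Cursor offsets are 0-based, half-open spans; keywords are matched
  case-insensitively and suggested upper-case.
- The grammar subset is SELECT-only; CONSTRUCT/ASK/DESCRIBE, property paths,
  subqueries and aggregation are out of scope, and FILTER expressions are
  consumed opaquely (no completion inside them).
- Parse errors carry the offset of the first offending token; a malformed
  token *at* the cursor is treated as the token being typed, not an error.
- FROM documents are fetched at most once per engine session through a
  pluggable fetcher; fetch or parse failures are logged and skipped so
  completion never fails because an ontology was unreachable.
- Registry filtering removes only properties known *solely* from the
  registry when they are unserviceable for the clause subject;
  ontology-indexed properties are never filtered, only left unhighlighted.
  With no type information for the subject, nothing is filtered or
  highlighted.
- No PREFIX declaration is auto-inserted when a term needs a full IRI.

## Verification

Three independent oracles back the property suites: (a) the partial parser is
checked against a brute-force enumeration of every valid query of the subset
grammar over a tiny vocabulary (prefixes up to 8 tokens; SELECT lists capped
at three variables in the enumeration), asserting the reported position is
always completable and no completable role is missed; (b) type propagation is
checked against an exhaustive derivation closure on 200 random ≤10-triple /
≤10-record instances; (c) label matching is checked against a brute-force
scan of every label on 100 random fixtures, alongside merge idempotence,
JSON round-trip identity and language completeness.  These sizes keep the
full suite under a few seconds while exercising every code path; the
acceptance script re-runs the same computations and reports agreement rates.

## Known limitations

Exact-IRI matchmaking cannot recognize a service whose input is a class
expression or a superclass of the subject's type.  The parser's position is
single-valued; where several roles are grammatically completable (after a
SELECT variable, say, where another variable or FROM/WHERE may follow) the
term position is reported and keywords are carried separately as candidates.
Description-only matches always rank below label matches, which is a design
choice, not an observed property of any particular deployment.  The REPL is
line-oriented rather than per-keystroke.
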
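# sparql-complete

Context-sensitive, language-neutral type-ahead completion for SPARQL SELECT
queries.

## The problem

Life-science ontologies increasingly follow the best practice of *opaque*
identifiers: `sio:SIO_000062` is stable across ontology evolution and neutral
across languages, but it is meaningless to the person writing a query, and a
WHERE clause full of such URIs is effectively impossible to compose by hand.
`sparql-complete` lets a user write queries through the human-readable,
language-tagged labels those terms carry (`rdfs:label`, `skos:prefLabel`, …)
and performs the translation to opaque URIs automatically.

The package is aimed at bioinformaticians and tool builders who need query
assistance over RDF vocabularies (SIO-style predicate ontologies, LSRN/KEGG
record identifiers, …), whether embedded in an application or driven from the
shell.

## What it does

Given the query text typed so far and a cursor offset, the engine

1. **incrementally parses** the partial SELECT query — grammar subset
   `PREFIX* SELECT [DISTINCT] (?var+ | *) FROM* WHERE { BGP }` with
   OPTIONAL/UNION groups and opaque FILTER expressions — and determines the
   grammatical role completable at the cursor, plus the declared prefixes,
   variables and triple patterns `(s, p, o)`;
2. **looks candidates up** in a multilingual label index built from OWL/RDF
   documents (RDF/XML or Turtle), JSON preload indexes, or ontologies named
   in the query's own FROM clauses (fetched and indexed on the fly);
3. **ranks** them — previously declared variables first in subject/object
   slots, then label matches by grade (label prefix < word prefix < label
   substring < description substring); and
4. on acceptance **rewrites the query**, splicing in the prefixed name or
   `<uri>` form of the chosen term.

With a SADI-style service registry configured (records *input class →
attached property → output class*), predicates that a registered service can
generate for the clause subject's semantic type are highlighted and floated
to the top, and the service's output class is propagated (to fixpoint) onto
the object variable so that subsequent clauses are matched too.

## Worked example

```python
from sparql_complete.fixtures import SIO, walkthrough_fixture

engine = walkthrough_fixture().engine()
q = f"PREFIX SIO: <{SIO}> SELECT ?gene ?protein WHERE {{ ?gene "

for s in engine.suggest(q + "parti"):
    print(s.display, "->", s.insertion)
```

prints

```
has participant -> SIO:SIO_000132
is participant in -> SIO:SIO_000062
```

— the two indexed predicates whose label contains a word starting with
"parti", each carrying its description so the user can choose; accepting the
second one yields the query text `… WHERE { ?gene SIO:SIO_000062 ` with the
opaque URI substituted for the label.  The `examples/` directory contains
four short narrative scripts: building a multilingual index, a complete
type-ahead session, registry highlighting with type propagation, and the
English/German language-neutrality demonstration.

## Command line

```
sparql-complete index props.en.ttl kegg.ttl --out index.json
sparql-complete complete "pr" --cursor 2 --ontology props.en.ttl
sparql-complete repl --ontology props.en.ttl --registry registry.json
```

`complete` prints the ranked suggestions as JSON; `repl` is a line-oriented
composer (`+ text`, `?`, `!N`, `.`) that also works under a pipe.

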
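"""Compose a SPARQL query step by step with type-ahead completion.

At each step the engine parses the partial query, works out what is
grammatically completable at the cursor, and ranks candidates; accepting a
suggestion splices the term's opaque URI (prefixed name where a declared
PREFIX covers it) into the query.
"""

from sparql_complete.fixtures import SIO, walkthrough_fixture

engine = walkthrough_fixture().engine()

# The first thing a query needs is a keyword.
print("typed 'pr'      ->", [s.display for s in engine.suggest("pr", 2)])

q = f"PREFIX SIO: <{SIO}> SELECT ?gene ?protein WHERE {{ "

# Declared variables are suggested in subject position.
print("typed '?g'      ->", [s.display for s in engine.suggest(q + '?g')])
q += "?gene "

# Predicates are found through their human-readable labels.
suggestions = engine.suggest(q + "parti")
print("typed 'parti'   ->", [s.display for s in suggestions])
chosen = [s for s in suggestions if s.display == "is participant in"][0]
q, _ = engine.apply_suggestion(q + "parti", None, chosen)
print("accepted        ->", q.split("{")[1].strip())

# Named individuals too: the label becomes a full IRI on acceptance.
suggestions = engine.suggest(q + "caff")
print("typed 'caff'    ->", [s.display for s in suggestions])
q, _ = engine.apply_suggestion(q + "caff", None, suggestions[0])
print("\nfinal clause:", q.split("{")[1].strip())
# The clause now reads entirely in opaque identifiers, ready for any
# SPARQL endpoint, while composition happened entirely in English.
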
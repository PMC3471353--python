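"""Service-registry matchmaking: highlight answerable predicates and
propagate semantic types across clauses.

With a SADI-style registry configured, a predicate attached by a service
that accepts the clause subject's semantic type is highlighted — assurance
the clause can actually be resolved.  The service's declared output type is
assigned to the object variable, so the *next* clause is matched too.
"""

from sparql_complete.fixtures import CAFFEINE_PATHWAY, SIO, walkthrough_fixture

# registry configured; German label extension pre-loaded so the codes-for
# predicate ("codiert für") is findable in clause 2
engine = walkthrough_fixture().engine(german=True)

q = f"PREFIX SIO: <{SIO}> SELECT ?gene ?protein WHERE {{ <{CAFFEINE_PATHWAY}> "

print("clause 1 subject is the (typed) caffeine-metabolism pathway")
for s in engine.suggest(q + "parti"):
    mark = "* " if s.highlighted else "  "
    print(f"  {mark}{s.display}")
print("(* = a registered service can generate this predicate for that input)")

sel = [s for s in engine.suggest(q + "parti") if s.display == "has participant"][0]
q, _ = engine.apply_suggestion(q + "parti", None, sel)
q += "?gene . ?gene "

print("\nclause 2 subject is ?gene, typed by the first service's output")
for s in engine.suggest(q + "codiert"):
    mark = "* " if s.highlighted else "  "
    print(f"  {mark}{s.display}")
# The codes-for predicate is highlighted although ?gene is only a variable:
# the registry said clause 1's service outputs gene records.
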
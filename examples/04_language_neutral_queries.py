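"""Internationalization: the same query composed in English and in German.

Labels are views onto opaque URIs, so accepting "has participant" or
"hat Beteiligten" produces byte-identical SPARQL.  The German labels arrive
dynamically through a FROM clause naming a label-extension ontology.
"""

from sparql_complete.fixtures import (
    CAFFEINE_PATHWAY,
    GERMAN_EXTENSION_IRI,
    SIO,
    walkthrough_fixture,
)

engine = walkthrough_fixture().engine()

head = (
    f"PREFIX SIO: <{SIO}> SELECT ?gene FROM <{GERMAN_EXTENSION_IRI}> "
    f"WHERE {{ <{CAFFEINE_PATHWAY}> "
)

s_en = [s for s in engine.suggest(head + "parti") if s.display == "has participant"][0]
q_en, _ = engine.apply_suggestion(head + "parti", None, s_en)

s_de = [s for s in engine.suggest(head + "Bet") if s.display == "hat Beteiligten"][0]
q_de, _ = engine.apply_suggestion(head + "Bet", None, s_de)

print("accepted (en):", s_en.display, "->", s_en.target_uri)
print("accepted (de):", s_de.display, "->", s_de.target_uri)
print("queries byte-identical:", q_en == q_de)
print("clause:", q_en.split("{", 1)[1].strip())
# Identical output regardless of the language the user composed in.
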
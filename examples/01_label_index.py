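"""Build a multilingual label index from RDF and look terms up.

Ontologies that follow best practice use opaque URIs (SIO_000062 tells a
human nothing); the index maps typed text to terms through their
language-tagged labels instead.
"""

import io

from sparql_complete import TermIndex
from sparql_complete.fixtures import walkthrough_fixture

fx = walkthrough_fixture()
index = TermIndex()
index.index_ontology(io.StringIO(fx.ontologies["props.en.ttl"]), fmt="turtle")
index.index_ontology(io.StringIO(fx.ontologies["kegg.ttl"]), fmt="turtle")
index.index_ontology(io.StringIO(fx.ontologies["props.de.ttl"]), fmt="turtle")

print(f"indexed {len(index.terms)} terms")

print("\nEnglish lookup 'parti' (property):")
for m in index.match_terms("parti", kind="property"):
    print(f"  grade {m.grade}: {m.label!r} -> {m.term.uri}")

print("\nGerman lookup 'Bet' (property, lang=de):")
for m in index.match_terms("Bet", kind="property", lang="de"):
    print(f"  grade {m.grade}: {m.label!r} -> {m.term.uri}")

# Both languages resolve to the same opaque URI: the label is just a view.
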
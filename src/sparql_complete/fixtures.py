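"""Deterministic test vocabularies: a canonical walkthrough fixture and a
seeded random-ontology generator.

Everything here is synthetic.  The walkthrough fixture emulates a small
slice of the SIO predicate vocabulary and a KEGG pathway individual — enough
to exercise multilingual labelling, naming collisions, opaque-URI
substitution and registry matchmaking — but it is not the real SIO or KEGG,
and its description strings (plus the ``SIO_010078`` codes-for placeholder
URI) are invented for testing.  No network access is ever required.
"""

from __future__ import annotations

import io
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import rdflib

from .engine import CompletionEngine
from .index import TermIndex, load_json_index
from .registry import Registry

# --------------------------------------------------------------------- URIs

SIO = "http://semanticscience.org/resource/"
LSRN_SCHEMA = "http://purl.oclc.org/SADI/LSRN/"

IS_PARTICIPANT_IN = SIO + "SIO_000062"
HAS_PARTICIPANT = SIO + "SIO_000132"
IS_ENCODED_BY = SIO + "SIO_010079"
#: Synthetic placeholder for the "codes for" predicate; do not rely on the
#: exact URI.
CODES_FOR = SIO + "SIO_010078"
IS_ENCODED_BY_COLLIDING = "http://example.org/genomics/isEncodedBy"

KEGG_PATHWAY_NS = "http://lsrn.org/KEGG_PATHWAY:"
CAFFEINE_PATHWAY = KEGG_PATHWAY_NS + "hsa00232"

PATHWAY_CLASS = LSRN_SCHEMA + "KEGG_PATHWAY_Record"
GENE_CLASS = LSRN_SCHEMA + "KEGG_GENE_Record"
PROTEIN_CLASS = LSRN_SCHEMA + "UniProt_Record"

#: IRI used in FROM clauses to pull in the German label-extension document.
GERMAN_EXTENSION_IRI = "http://example.org/ontologies/props.de.owl"

_PROPS_EN_TTL = f"""\
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix sio: <{SIO}> .
@prefix ex: <http://example.org/genomics/> .

sio:SIO_000062 a owl:ObjectProperty ;
    rdfs:label "is participant in"@en ;
    rdfs:comment "A relation between an entity and the process it takes part in (synthetic definition)."@en .

sio:SIO_000132 a owl:ObjectProperty ;
    rdfs:label "has participant"@en ;
    rdfs:comment "A relation between a process and an entity taking part in it (synthetic definition)."@en .

sio:SIO_010079 a owl:ObjectProperty ;
    rdfs:label "is encoded by"@en .

sio:SIO_010078 a owl:ObjectProperty .

ex:isEncodedBy a owl:ObjectProperty ;
    rdfs:label "isEncodedBy" .
"""

_PROPS_DE_TTL = f"""\
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix sio: <{SIO}> .

sio:SIO_000132 rdfs:label "hat Beteiligten"@de .

sio:SIO_010078 rdfs:label "codiert für"@de .

<{CAFFEINE_PATHWAY}> rdfs:label "Stoffwechselweg Koffein menschlichen"@de .
"""

_KEGG_TTL = f"""\
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix lsrn: <{LSRN_SCHEMA}> .

<{CAFFEINE_PATHWAY}> a lsrn:KEGG_PATHWAY_Record ;
    rdfs:label "human caffeine metabolism pathway"@en ;
    rdfs:comment "Caffeine metabolism pathway in Homo sapiens (synthetic definition)."@en .

lsrn:KEGG_PATHWAY_Record a <http://www.w3.org/2002/07/owl#Class> ;
    rdfs:label "KEGG pathway record"@en .
lsrn:KEGG_GENE_Record a <http://www.w3.org/2002/07/owl#Class> ;
    rdfs:label "KEGG gene record"@en .
lsrn:UniProt_Record a <http://www.w3.org/2002/07/owl#Class> ;
    rdfs:label "UniProt protein record"@en .
"""

_REGISTRY = {
    "services": [
        {
            "id": "pathway-to-genes",
            "input_class": PATHWAY_CLASS,
            "property": HAS_PARTICIPANT,
            "output_class": GENE_CLASS,
        },
        {
            "id": "gene-codes-for-protein",
            "input_class": GENE_CLASS,
            "property": CODES_FOR,
            "output_class": PROTEIN_CLASS,
        },
    ]
}

_NAMESPACES = {
    "namespaces": [
        {"prefix": "SIO", "uri": SIO, "name": "Semanticscience Integrated Ontology"},
        {"prefix": "KEGG_PATHWAY", "uri": KEGG_PATHWAY_NS, "name": "KEGG Pathway"},
        {
            "prefix": "pc",
            "uri": "http://www.pathwaycommons.org/pc/",
            "name": "Pathway Commons",
        },
        {
            "prefix": "rdfs",
            "uri": "http://www.w3.org/2000/01/rdf-schema#",
            "name": "RDF Schema",
        },
        {"prefix": "lsrn", "uri": LSRN_SCHEMA, "name": "LSRN record schema"},
    ],
    "terms": [],
}


@dataclass
class WalkthroughFixture:
    """The walkthrough vocabulary as in-memory documents.

    ``ontologies`` maps file names to Turtle text; the German extension is
    additionally reachable through :meth:`fetcher` under
    :data:`GERMAN_EXTENSION_IRI` so FROM-clause resolution can be exercised
    without network access.
    """

    ontologies: dict[str, str]
    registry_json: str
    namespaces_json: str

    def build_index(self, german: bool = False) -> TermIndex:
        """Index the English documents (plus namespaces); with ``german=True``
        also merge the German label extension."""
        index = TermIndex()
        load_json_index(self.namespaces_json, index)
        for name in ("props.en.ttl", "kegg.ttl"):
            index.index_ontology(io.StringIO(self.ontologies[name]), fmt="turtle")
        if german:
            index.index_ontology(
                io.StringIO(self.ontologies["props.de.ttl"]), fmt="turtle"
            )
        return index

    def registry(self) -> Registry:
        return Registry.from_json(self.registry_json)

    def fetcher(self, iri: str) -> tuple[str, Optional[str]]:
        """Document fetcher mapping the German-extension IRI (and any
        ``fixture:`` name) to local documents."""
        if iri == GERMAN_EXTENSION_IRI:
            return self.ontologies["props.de.ttl"], "turtle"
        name = iri.rsplit("/", 1)[-1]
        if name in self.ontologies:
            return self.ontologies[name], "turtle"
        raise FileNotFoundError(iri)

    def engine(
        self,
        registry: bool = True,
        german: bool = False,
        lang: Optional[str] = None,
        max_suggestions: int = 10,
    ) -> CompletionEngine:
        return CompletionEngine(
            index=self.build_index(german=german),
            registry=self.registry() if registry else None,
            fetcher=self.fetcher,
            lang=lang,
            max_suggestions=max_suggestions,
        )

    def write(self, directory) -> dict[str, Path]:
        """Write every document (Turtle, RDF/XML variants, registry and
        namespace JSON) into a directory; byte-identical across calls."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, text in self.ontologies.items():
            path = directory / name
            path.write_text(text, encoding="utf-8")
            paths[name] = path
            # RDF/XML variant for parser coverage
            graph = rdflib.Graph()
            graph.parse(io.StringIO(text), format="turtle")
            xml_name = name.removesuffix(".ttl") + ".owl"
            xml_path = directory / xml_name
            xml_path.write_bytes(graph.serialize(format="pretty-xml").encode("utf-8"))
            paths[xml_name] = xml_path
        (directory / "registry.json").write_text(self.registry_json, encoding="utf-8")
        paths["registry.json"] = directory / "registry.json"
        (directory / "namespaces.json").write_text(
            self.namespaces_json, encoding="utf-8"
        )
        paths["namespaces.json"] = directory / "namespaces.json"
        return paths


def walkthrough_fixture() -> WalkthroughFixture:
    """The canonical fixture behind the worked examples: SIO-style predicates
    with English and German labels, a naming collision on "…encoded by…", a
    KEGG pathway individual, a two-service registry, and a namespace table."""
    return WalkthroughFixture(
        ontologies={
            "props.en.ttl": _PROPS_EN_TTL,
            "props.de.ttl": _PROPS_DE_TTL,
            "kegg.ttl": _KEGG_TTL,
        },
        registry_json=json.dumps(_REGISTRY, indent=2),
        namespaces_json=json.dumps(_NAMESPACES, indent=2, ensure_ascii=False),
    )


# ---------------------------------------------------------- random fixtures

_SYLLABLES = [
    "ba", "ce", "di", "fo", "gu", "ha", "ki", "lo", "mu", "ne",
    "pa", "qui", "ro", "su", "ta", "ve", "wi", "xa", "yo", "zu",
]


@dataclass
class FixtureSpec:
    """Shape of a generated ontology: term counts per kind, label languages,
    labels to duplicate across URIs, and the RNG seed."""

    n_properties: int = 5
    n_individuals: int = 3
    n_classes: int = 2
    languages: list[str] = field(default_factory=lambda: ["en"])
    collision_labels: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_properties, self.n_individuals, self.n_classes) < 0:
            raise ValueError("term counts must be >= 0")


def _word(rng: random.Random) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(2, 4)))


def _phrase(rng: random.Random) -> str:
    return " ".join(_word(rng) for _ in range(rng.randint(1, 3)))


def random_fixture(spec: FixtureSpec) -> str:
    """Generate a pseudo-random ontology (Turtle text), deterministic per
    seed.

    Each term gets one label per requested language (tagged unless the tag is
    empty); every collision label is additionally attached, untagged, to two
    distinct term URIs so lookup must surface both.
    """
    rng = random.Random(spec.seed)
    base = "http://example.org/random/"
    lines = [
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "",
    ]
    uris: list[str] = []
    decls = (
        ("property", "owl:ObjectProperty", spec.n_properties),
        ("individual", "owl:NamedIndividual", spec.n_individuals),
        ("class", "owl:Class", spec.n_classes),
    )
    for kind, rdf_type, count in decls:
        for i in range(count):
            uri = f"{base}{kind}_{spec.seed}_{i}"
            uris.append(uri)
            lines.append(f"<{uri}> a {rdf_type} ;")
            labels = []
            for tag in spec.languages:
                text = _phrase(rng)
                labels.append(f'"{text}"' + (f"@{tag}" if tag else ""))
            if rng.random() < 0.5:
                desc = _phrase(rng)
                lines.append(f'    rdfs:comment "{desc} (synthetic)" ;')
            lines.append("    rdfs:label " + ", ".join(labels) + " .")
            lines.append("")
    for label in spec.collision_labels:
        if len(uris) < 2:
            raise ValueError("collision labels need at least two terms")
        a, b = rng.sample(uris, 2)
        lines.append(f'<{a}> rdfs:label "{label}" .')
        lines.append(f'<{b}> rdfs:label "{label}" .')
        lines.append("")
    return "\n".join(lines)
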
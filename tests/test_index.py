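"""Unit and property tests for the label index."""

import io
import json

import pytest
import rdflib
from rdflib import RDFS

from sparql_complete.fixtures import (
    CAFFEINE_PATHWAY,
    HAS_PARTICIPANT,
    IS_ENCODED_BY,
    IS_PARTICIPANT_IN,
    FixtureSpec,
    random_fixture,
    walkthrough_fixture,
)
from sparql_complete.index import (
    IndexError_,
    LabeledTerm,
    TermIndex,
    export_json_index,
    load_json_index,
    local_name,
    match_label,
)

from conftest import index_of

SMALL_ONTOLOGY = """\
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix ex: <http://example.org/> .

ex:p1 a owl:ObjectProperty ; rdfs:label "binds to"@en .
ex:p2 a owl:ObjectProperty ; rdfs:label "regulates"@en .
ex:i1 a owl:NamedIndividual ; rdfs:label "lysozyme"@en .
"""


def brute_force_match(index, query, kind=None, lang=None):
    """Independent oracle: apply the matching rules to every label of every
    term and keep each URI's best hit."""
    hits = {}
    for uri, term in index.terms.items():
        if kind and term.kind != kind:
            continue
        best = None
        for text, tag in term.display_labels():
            if lang and tag and tag != lang:
                continue
            grade = match_label(text, query)
            if grade is not None and (
                best is None or (grade, text.casefold()) < best[:2]
            ):
                best = (grade, text.casefold(), uri)
        if best is None and query:
            for text, tag in term.descriptions:
                if lang and tag and tag != lang:
                    continue
                if query.casefold() in text.casefold():
                    labels = [
                        t
                        for t, g in sorted(term.display_labels())
                        if not (lang and g and g != lang)
                    ]
                    if labels:
                        best = (4, labels[0].casefold(), uri)
                    break
        if best:
            hits[uri] = best
    return sorted(hits.values())


class TestIndexOntology:
    def test_terms_match_raw_label_scan(self):
        """Every label triple in the document ends up on the right term."""
        index = index_of(SMALL_ONTOLOGY)
        graph = rdflib.Graph()
        graph.parse(io.StringIO(SMALL_ONTOLOGY), format="turtle")
        expected = {}
        for s, o in graph.subject_objects(RDFS.label):
            expected.setdefault(str(s), set()).add((str(o), o.language or ""))
        assert len(index.terms) == 3
        for uri, labels in expected.items():
            assert index.terms[uri].labels == labels
        kinds = {u: t.kind for u, t in index.terms.items()}
        assert kinds == {
            "http://example.org/p1": "property",
            "http://example.org/p2": "property",
            "http://example.org/i1": "individual",
        }

    def test_label_extension_merges_without_new_terms(self, walkthrough):
        """A German label-extension document adds labels to existing URIs but
        never new terms."""
        base = walkthrough.build_index()
        n = len(base.terms)
        base.index_ontology(
            io.StringIO(walkthrough.ontologies["props.de.ttl"]), fmt="turtle"
        )
        assert len(base.terms) == n
        assert ("hat Beteiligten", "de") in base.terms[HAS_PARTICIPANT].labels
        assert ("has participant", "en") in base.terms[HAS_PARTICIPANT].labels

    def test_unlabeled_term_indexed_under_local_name(self):
        index = index_of(
            "@prefix owl: <http://www.w3.org/2002/07/owl#> .\n"
            "<http://example.org/vocab#silentProp> a owl:ObjectProperty .\n"
        )
        [m] = index.match_terms("silent")
        assert m.term.uri == "http://example.org/vocab#silentProp"
        assert m.label == "silentProp"

    def test_merge_idempotence(self, walkthrough):
        once = walkthrough.build_index()
        twice = walkthrough.build_index()
        twice.index_ontology(
            io.StringIO(walkthrough.ontologies["props.en.ttl"]), fmt="turtle"
        )
        assert export_json_index(once) == export_json_index(twice)

    def test_unparseable_document_names_the_source(self, tmp_path):
        bad = tmp_path / "broken.ttl"
        bad.write_text("this is } not RDF @@@", encoding="utf-8")
        with pytest.raises(IndexError_, match="broken.ttl"):
            TermIndex().index_ontology(str(bad), fmt="turtle")

    def test_empty_document_leaves_index_unchanged(self, walkthrough):
        index = walkthrough.build_index()
        before = export_json_index(index)
        index.index_ontology(io.StringIO(""), fmt="turtle")
        assert export_json_index(index) == before

    def test_rdfxml_and_turtle_yield_same_index(self, walkthrough, tmp_path):
        paths = walkthrough.write(tmp_path)
        ttl = TermIndex().index_ontology(str(paths["props.en.ttl"]), fmt="turtle")
        xml = TermIndex().index_ontology(str(paths["props.en.owl"]), fmt="xml")
        assert export_json_index(ttl) == export_json_index(xml)


class TestMatchTerms:
    def test_parti_returns_the_two_participation_predicates(self, wt_index):
        hits = wt_index.match_terms("parti", kind="property")
        assert [m.term.uri for m in hits] == [HAS_PARTICIPANT, IS_PARTICIPANT_IN]
        assert [m.label for m in hits] == ["has participant", "is participant in"]

    def test_empty_query_returns_all_terms_deterministically(self, wt_index):
        hits = wt_index.match_terms("")
        assert {m.term.uri for m in hits} == set(wt_index.terms)
        assert hits == wt_index.match_terms("")

    def test_german_label_lookup_with_lang_filter(self, wt_index_de):
        hits = wt_index_de.match_terms("Bet", kind="property", lang="de")
        assert [m.term.uri for m in hits] == [HAS_PARTICIPANT]
        assert hits[0].label == "hat Beteiligten"

    def test_lang_filter_excludes_other_tagged_labels(self, wt_index_de):
        # "has participant"@en must not surface under a German filter
        hits = wt_index_de.match_terms("has par", kind="property", lang="de")
        assert hits == []

    def test_untagged_labels_match_any_lang_filter(self, wt_index):
        # "isEncodedBy" is untagged, so it qualifies even under @de
        hits = wt_index.match_terms("isEnc", kind="property", lang="de")
        assert [m.label for m in hits] == ["isEncodedBy"]

    def test_description_matches_rank_below_label_matches(self, wt_index):
        # "relation" appears only in the synthetic descriptions
        hits = wt_index.match_terms("relation between", kind="property")
        assert hits and all(m.grade == 4 for m in hits)

    def test_same_uri_appears_once_with_best_label(self, wt_index_de):
        hits = wt_index_de.match_terms("", kind="property")
        uris = [m.term.uri for m in hits]
        assert len(uris) == len(set(uris))

    def test_caffeine_individual_found_by_word_prefix(self, wt_index):
        hits = wt_index.match_terms("caff", kind="individual")
        assert [m.term.uri for m in hits] == [CAFFEINE_PATHWAY]
        assert hits[0].grade == 2

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_on_random_fixtures(self, seed):
        """match_terms agrees with a brute-force scan of every label."""
        spec = FixtureSpec(
            n_properties=4,
            n_individuals=3,
            n_classes=2,
            languages=["en", "de", ""],
            collision_labels=["shared label"],
            seed=seed,
        )
        index = index_of(random_fixture(spec))
        queries = [""] + [
            lab[0][0][:n]
            for t in index.terms.values()
            for lab in [sorted(t.labels)[:1]]
            if lab
            for n in (1, 3)
        ]
        for q in queries[:12]:
            for kind in (None, "property"):
                for lang in (None, "de"):
                    got = [
                        (m.grade, m.label.casefold(), m.term.uri)
                        for m in index.match_terms(q, kind=kind, lang=lang)
                    ]
                    assert sorted(got) == brute_force_match(index, q, kind, lang)

    def test_language_completeness(self, wt_index_de):
        """A term labelled in two languages is reachable through either,
        resolving to the same URI."""
        en = wt_index_de.match_terms("has participant", lang="en")
        de = wt_index_de.match_terms("hat Beteiligten", lang="de")
        assert [m.term.uri for m in en] == [m.term.uri for m in de] == [HAS_PARTICIPANT]

    def test_fallback_totality(self, wt_index_de):
        """Every indexed term is findable by its best label or local name."""
        for term in wt_index_de.terms.values():
            probe = term.display_labels()[0][0]
            hits = wt_index_de.match_terms(probe)
            assert term.uri in {m.term.uri for m in hits}


class TestMatchNamespaces:
    def test_path_finds_the_kegg_pathway_namespace(self, wt_index):
        names = [ns.display_name for ns in wt_index.match_namespaces("path")]
        assert "KEGG Pathway" in names

    def test_empty_query_returns_all_namespaces(self, wt_index):
        assert len(wt_index.match_namespaces("")) == len(wt_index.namespaces)

    def test_no_match_returns_empty_list(self, wt_index):
        assert wt_index.match_namespaces("zzz-no-such") == []


class TestJsonRoundTrip:
    def test_load_export_identity_on_observable_content(self, wt_index_de):
        reloaded = load_json_index(export_json_index(wt_index_de))
        assert export_json_index(reloaded) == export_json_index(wt_index_de)
        for q in ("parti", "caff", "code", ""):
            a = [(m.grade, m.label, m.term.uri) for m in wt_index_de.match_terms(q)]
            b = [(m.grade, m.label, m.term.uri) for m in reloaded.match_terms(q)]
            assert a == b

    def test_missing_uri_reports_offending_path(self):
        doc = json.dumps({"namespaces": [], "terms": [{"kind": "property"}]})
        with pytest.raises(IndexError_, match=r"terms\[0\].uri"):
            load_json_index(doc)

    def test_namespace_only_document(self):
        doc = json.dumps(
            {"namespaces": [{"prefix": "ex", "uri": "http://e/", "name": "E"}],
             "terms": []}
        )
        index = load_json_index(doc)
        assert len(index.namespaces) == 1 and len(index.terms) == 0

    def test_unknown_keys_warn_but_load(self, caplog):
        doc = json.dumps(
            {"namespaces": [], "terms": [], "extra": 1},
        )
        with caplog.at_level("WARNING"):
            load_json_index(doc)
        assert any("extra" in r.message for r in caplog.records)

    def test_invalid_kind_rejected(self):
        doc = json.dumps(
            {"terms": [{"uri": "http://e/x", "kind": "widget"}], "namespaces": []}
        )
        with pytest.raises(IndexError_, match="kind"):
            load_json_index(doc)


def test_local_name_handles_hash_slash_and_colon():
    assert local_name("http://e/vocab#thing") == "thing"
    assert local_name("http://e/vocab/thing") == "thing"
    assert local_name("http://lsrn.org/KEGG_PATHWAY:hsa00232") == "KEGG_PATHWAY:hsa00232"


def test_labeled_term_rejects_bad_kind():
    with pytest.raises(ValueError):
        LabeledTerm("http://e/x", "gadget")
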
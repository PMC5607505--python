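"""Query text generation: federated, star-shaped, profile and property-list."""

import pytest
from hypothesis import given, settings, strategies as st
from rdflib import Graph

from fedsim import fixtures
from fedsim.querygen import (
    QueryGenerationError,
    QueryPattern,
    build_profile_query,
    build_property_list_query,
    build_star_query,
    count_triple_patterns,
    escape_literal,
    instantiate_query,
    validate_sparql,
)
from fedsim.registry import Template, resolve_template

KEYWORD = fixtures.CANONICAL_INCHIKEY


class TestQueryPattern:
    def test_placeholder_count_by_scanning(self):
        p = QueryPattern(text="SELECT * WHERE { ?s ?p \"%s\" . %s }")
        assert p.placeholder_count == 2

    def test_tail_reserved_requires_a_placeholder(self):
        with pytest.raises(ValueError):
            QueryPattern(text="SELECT * WHERE { ?s ?p ?o }", tail_reserved=True)


class TestInstantiateQuery:
    def test_predefined_query_has_four_service_blocks(self, registry):
        t1 = resolve_template(registry, "Biology", "Targets", 1)
        q = instantiate_query(t1, KEYWORD)
        assert q.text.count("SERVICE SILENT") == 4
        assert "%s" not in q.text
        assert KEYWORD in q.text
        validate_sparql(q.text)
        assert [s.name for s in q.sources] == [
            "PIBAS", "ChEMBL", "BindingDB", "Drugbank",
        ]

    def test_added_dataset_fills_the_tail_placeholder(self, registry):
        t1 = resolve_template(registry, "Biology", "Targets", 1)
        q = instantiate_query(t1, KEYWORD, added=fixtures.test_dataset_spec())
        assert q.text.count("SERVICE SILENT") == 5
        assert "%s" not in q.text
        validate_sparql(q.text)
        assert q.sources[-1].name == "Test"
        assert len(q.source_patterns) == 5

    def test_keyword_quotes_are_escaped_not_injected(self, registry):
        t1 = resolve_template(registry, "Biology", "Targets", 1)
        hostile = 'x" } SERVICE <http://evil/> { ?s ?p "y'
        q = instantiate_query(t1, hostile)
        # the query still parses and the quote is escaped inside the literal
        validate_sparql(q.text)
        assert '\\"' in q.text
        assert q.text.count("SERVICE SILENT") == 4

    def test_empty_keyword_rejected(self, registry):
        t1 = resolve_template(registry, "Biology", "Targets", 1)
        with pytest.raises(ValueError):
            instantiate_query(t1, "   ")

    def test_pattern_without_placeholders_passes_through(self):
        text = "SELECT ?Target WHERE { ?Target a <http://example.org/T> . }"
        template = Template(
            label=9,
            name="static",
            keyword_kind="unrestricted",
            result_variable="Target",
            initial_query_pattern=QueryPattern(text=text, tail_reserved=False),
            connected_datasets=[],
        )
        q = instantiate_query(template, "anything")
        assert q.text == text

    def test_added_pattern_must_bind_result_variable(self, registry):
        import dataclasses

        t1 = resolve_template(registry, "Biology", "Targets", 1)
        bad = dataclasses.replace(
            fixtures.test_dataset_spec(),
            pattern_query='?drug <http://example.org/key> "%s" .',
        )
        with pytest.raises(QueryGenerationError, match=r"\?Target"):
            instantiate_query(t1, KEYWORD, added=bad)


class TestEscaping:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ('say "hi"', 'say \\"hi\\"'),
            ("back\\slash", "back\\\\slash"),
            ("line\nbreak", "line\\nbreak"),
        ],
    )
    def test_escape_literal(self, raw, expected):
        assert escape_literal(raw) == expected


ANCHOR = "?Target <http://chem2bio2rdf.org/bindingdb/resource/TARGET> ?anchor0"


class TestStarQuery:
    def test_two_properties_give_three_triple_patterns(self, registry):
        t1 = resolve_template(registry, "Biology", "Targets", 1)
        bdb = t1.connected_datasets[2]
        star = build_star_query(
            bdb,
            "Target",
            [
                "http://chem2bio2rdf.org/bindingdb/resource/CID_GENE",
                "http://chem2bio2rdf.org/bindingdb/resource/uniprot",
            ],
            ANCHOR,
        )
        assert star.k == 2
        assert count_triple_patterns(star.text) == 3
        assert "?o1" in star.text and "?o2" in star.text

    def test_single_property_gives_two_patterns(self, registry):
        t1 = resolve_template(registry, "Biology", "Targets", 1)
        star = build_star_query(
            t1.connected_datasets[2], "Target", ["http://example.org/p"], ANCHOR
        )
        assert count_triple_patterns(star.text) == 2

    def test_empty_properties_rejected(self, registry):
        t1 = resolve_template(registry, "Biology", "Targets", 1)
        with pytest.raises(ValueError, match="at least one property"):
            build_star_query(t1.connected_datasets[2], "Target", [], ANCHOR)

    def test_anchor_must_share_the_subject_variable(self, registry):
        t1 = resolve_template(registry, "Biology", "Targets", 1)
        with pytest.raises(QueryGenerationError, match="subject"):
            build_star_query(
                t1.connected_datasets[2],
                "Target",
                ["http://example.org/p"],
                "?other <http://example.org/q> ?x",
            )

    @settings(derandomize=True, max_examples=25)
    @given(k=st.integers(min_value=1, max_value=10))
    def test_star_arity_is_k_plus_one(self, registry, k):
        t1 = resolve_template(registry, "Biology", "Targets", 1)
        props = [f"http://example.org/prop{i}" for i in range(k)]
        star = build_star_query(t1.connected_datasets[0], "Target", props,
                                "?Target a <http://example.org/T>")
        assert count_triple_patterns(star.text) == k + 1
        # all k+1 patterns share one subject variable
        assert star.text.count("?Target") >= k + 1


class TestProfileQuery:
    def test_single_subject_term(self, uri_of):
        text = build_profile_query(uri_of("URI_1"))
        assert text.count(f"<{uri_of('URI_1')}>") == 1
        validate_sparql(text)

    @pytest.mark.parametrize("bad", ["not a uri", "relative/path", "<wrapped>"])
    def test_invalid_uri_rejected(self, bad):
        with pytest.raises(ValueError):
            build_profile_query(bad)

    def test_profile_query_on_fixture_graph(self, bundle, uri_of):
        g = Graph()
        g.parse(str(bundle.graph_paths["PIBAS/CPCTAS"]))
        rows = list(g.query(build_profile_query(uri_of("URI_1"))))
        values = {str(o) for _, o in rows}
        assert "MAPKAP kinase 2" in values
        assert "MAPK-activated protein kinase 2" in values

    def test_absent_uri_yields_zero_rows(self, bundle):
        g = Graph()
        g.parse(str(bundle.graph_paths["PIBAS/CPCTAS"]))
        rows = list(g.query(build_profile_query("http://example.org/nothing")))
        assert rows == []


class TestPropertyListQuery:
    def _props(self, bundle, registry, dataset_index, key):
        t1 = resolve_template(registry, "Biology", "Targets", 1)
        ds = t1.connected_datasets[dataset_index]
        text = build_property_list_query(ds, t1)
        g = Graph()
        g.parse(str(bundle.graph_paths[key]))
        return {str(row[0]) for row in g.query(text)}

    def test_pibas_properties_include_name_and_synonym(self, bundle, registry):
        props = self._props(bundle, registry, 0, "PIBAS/CPCTAS")
        assert "http://cpctas-lcmb.pmf.kg.ac.rs/2012/3/PIBAS#hasTargetName" in props
        assert "http://cpctas-lcmb.pmf.kg.ac.rs/2012/3/PIBAS#hasSynonym" in props

    def test_bindingdb_properties_include_target(self, bundle, registry):
        props = self._props(bundle, registry, 2, "BindingDB/Chem2Bio2RDF")
        assert "http://chem2bio2rdf.org/bindingdb/resource/TARGET" in props

    def test_empty_graph_gives_empty_list(self, registry, tmp_path):
        t1 = resolve_template(registry, "Biology", "Targets", 1)
        text = build_property_list_query(t1.connected_datasets[0], t1)
        assert list(Graph().query(text)) == []

    def test_unconnected_dataset_rejected(self, registry):
        t1 = resolve_template(registry, "Biology", "Targets", 1)
        with pytest.raises(ValueError, match="not connected"):
            build_property_list_query(fixtures.test_dataset_spec(), t1)
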
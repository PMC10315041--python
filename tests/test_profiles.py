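"""Profile parsing, SHACL shape generation, selection, validation and
humanized reporting."""

import pytest
from hypothesis import given, settings, strategies as st
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from fairchecker.errors import ProfileParseError
from fairchecker.fixtures import (make_gene_entity_graph,
                                  make_profile_document)
from fairchecker.namespaces import DCT, SCHEMA, SH
from fairchecker.profiles import (ProfileSpec, builtin_profiles,
                                  generate_shape, generate_shape_text,
                                  humanize, parse_profile, select_profile,
                                  validate)

SCHEMA_S = str(SCHEMA)


class TestParseProfile:
    def test_gene_profile_buckets(self, gene_profile):
        assert set(gene_profile.minimum_properties) == {
            SCHEMA_S + "identifier", SCHEMA_S + "name"}
        assert set(gene_profile.recommended_properties) == {
            SCHEMA_S + "description", SCHEMA_S + "url"}

    def test_empty_recommended_is_valid(self):
        document = make_profile_document("Minimal", SCHEMA_S + "Thing",
                                         [SCHEMA_S + "name"], [])
        spec = parse_profile(document)
        assert spec.recommended_properties == ()

    def test_missing_target_class_rejected(self):
        with pytest.raises(ProfileParseError):
            parse_profile('{"name": "X", "properties": []}')

    def test_unknown_marginality_label_named_in_error(self):
        document = ('{"name": "X", "targetClass": "http://schema.org/Thing",'
                    '"properties": [{"property": "http://schema.org/name",'
                    '"marginality": "mandatoryish"}]}')
        with pytest.raises(ProfileParseError, match="mandatoryish"):
            parse_profile(document)

    def test_overlapping_buckets_rejected(self):
        with pytest.raises(ProfileParseError):
            make_profile_document("X", SCHEMA_S + "Thing",
                                  [SCHEMA_S + "name"], [SCHEMA_S + "name"])

    def test_document_round_trip(self):
        document = make_profile_document(
            "GeneLike", SCHEMA_S + "Gene",
            [SCHEMA_S + "identifier", SCHEMA_S + "name"],
            [SCHEMA_S + "description", SCHEMA_S + "url"],
            optional_props=[SCHEMA_S + "alternateName"])
        spec = parse_profile(document)
        assert spec.minimum_properties == (SCHEMA_S + "identifier",
                                           SCHEMA_S + "name")
        assert spec.recommended_properties == (SCHEMA_S + "description",
                                               SCHEMA_S + "url")
        assert spec.optional_properties == (SCHEMA_S + "alternateName",)


_props = st.lists(
    st.sampled_from([SCHEMA_S + local for local in (
        "name", "description", "url", "identifier", "version", "citation",
        "license", "keywords", "creator", "provider")]),
    unique=True, max_size=8)


class TestGenerateShape:
    def _severity_counts(self, shape: Graph):
        severities = [o for _, _, o in shape.triples((None, SH.severity, None))]
        return (sum(1 for s in severities if s == SH.Violation),
                sum(1 for s in severities if s == SH.Warning))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(_props, _props)
    def test_shape_count_law(self, pool_a, pool_b):
        """One Violation property shape per minimum property, one Warning
        shape per recommended property, for any profile."""
        minimum = tuple(p for p in pool_a if p not in pool_b)
        recommended = tuple(pool_b)
        spec = ProfileSpec("Random", "https://profiles.example.org/Random",
                           SCHEMA_S + "Thing", minimum, recommended)
        violations, warnings = self._severity_counts(generate_shape(spec))
        assert violations == len(minimum)
        assert warnings == len(recommended)

    def test_gene_shape_severities_by_property(self, gene_profile):
        shape = generate_shape(gene_profile)
        by_path = {}
        for prop_shape in shape.objects(None, SH.property):
            path = str(shape.value(prop_shape, SH.path))
            by_path[path] = shape.value(prop_shape, SH.severity)
        assert by_path[SCHEMA_S + "identifier"] == SH.Violation
        assert by_path[SCHEMA_S + "name"] == SH.Violation
        assert by_path[SCHEMA_S + "description"] == SH.Warning
        assert by_path[SCHEMA_S + "url"] == SH.Warning

    def test_shape_text_is_bit_stable(self, tool_profile):
        assert generate_shape_text(tool_profile) == generate_shape_text(tool_profile)

    def test_empty_recommended_yields_no_warning_shapes(self):
        spec = ProfileSpec("X", "https://profiles.example.org/X",
                           SCHEMA_S + "Thing", (SCHEMA_S + "name",), ())
        assert self._severity_counts(generate_shape(spec)) == (1, 0)


class TestSelectProfile:
    def test_conforms_to_declaration_wins(self, gene_profile, tool_profile):
        graph = Graph()
        entity = URIRef("http://x.org/e")
        graph.add((entity, DCT.conformsTo, URIRef(gene_profile.source_url)))
        chosen = select_profile(graph, entity, [tool_profile, gene_profile])
        assert chosen is gene_profile

    def test_type_based_selection(self, tool_profile, gene_profile):
        graph = Graph()
        entity = URIRef("http://x.org/tool")
        graph.add((entity, RDF.type, SCHEMA.SoftwareApplication))
        chosen = select_profile(graph, entity, [gene_profile, tool_profile])
        assert chosen is tool_profile

    def test_unmatched_type_gives_none(self, tool_profile):
        graph = Graph()
        entity = URIRef("http://x.org/e")
        graph.add((entity, RDF.type, SCHEMA.Recipe))
        assert select_profile(graph, entity, [tool_profile]) is None

    def test_tie_broken_by_present_minimum_properties(self):
        twin_a = ProfileSpec("Alpha", "https://p.example/a", SCHEMA_S + "Thing",
                             (SCHEMA_S + "name",), ())
        twin_b = ProfileSpec("Beta", "https://p.example/b", SCHEMA_S + "Thing",
                             (SCHEMA_S + "version",), ())
        graph = Graph()
        entity = URIRef("http://x.org/e")
        graph.add((entity, RDF.type, SCHEMA.Thing))
        graph.add((entity, SCHEMA.version, Literal("2")))
        assert select_profile(graph, entity, [twin_a, twin_b]).name == "Beta"
        # with no distinguishing property, the lexicographic name wins
        graph.remove((entity, SCHEMA.version, Literal("2")))
        assert select_profile(graph, entity, [twin_b, twin_a]).name == "Alpha"


class TestValidate:
    def test_complete_entity_is_conformant(self, gene_profile):
        graph = make_gene_entity_graph(
            properties=("identifier", "name", "description", "url"))
        report = validate(graph, generate_shape(gene_profile),
                          profile=gene_profile)
        assert report.conforms
        assert report.violations == () and report.warnings == ()

    def test_gene_with_minimum_only_warns_twice(self, gene_profile):
        graph = make_gene_entity_graph(properties=("identifier", "name"))
        report = validate(graph, generate_shape(gene_profile),
                          profile=gene_profile)
        assert report.conforms
        assert len(report.warnings) == 2
        warned = {p for _, p in report.warnings}
        assert warned == {SCHEMA_S + "description", SCHEMA_S + "url"}

    @pytest.mark.parametrize("profile_name", ["Gene", "ComputationalTool"])
    def test_removal_law(self, profile_name):
        """Deleting all triples of one minimum property from a conformant
        entity yields exactly one violation naming it; likewise one warning
        per deleted recommended property — exhaustively over the profile."""
        spec = next(p for p in builtin_profiles() if p.name == profile_name)
        shape = generate_shape(spec)
        entity = URIRef("http://x.org/entity")

        def complete_graph():
            graph = Graph()
            graph.add((entity, RDF.type, URIRef(spec.target_class)))
            for prop in spec.minimum_properties + spec.recommended_properties:
                graph.add((entity, URIRef(prop), Literal("value")))
            return graph

        baseline = validate(complete_graph(), shape, profile=spec)
        assert baseline.conforms and baseline.warnings == ()

        for prop in spec.minimum_properties:
            graph = complete_graph()
            graph.remove((entity, URIRef(prop), None))
            report = validate(graph, shape, profile=spec)
            assert [p for _, p in report.violations] == [prop]
            assert report.warnings == ()
        for prop in spec.recommended_properties:
            graph = complete_graph()
            graph.remove((entity, URIRef(prop), None))
            report = validate(graph, shape, profile=spec)
            assert report.violations == ()
            assert [p for _, p in report.warnings] == [prop]

    def test_validation_monotone_under_additions(self, gene_profile):
        graph = make_gene_entity_graph(properties=("identifier",))
        shape = generate_shape(gene_profile)
        before = validate(graph, shape, profile=gene_profile)
        graph.add((URIRef("http://x.org/other"), SCHEMA.name, Literal("n")))
        graph.add((URIRef("https://example.org/gene/BRCA1"), SCHEMA.name,
                   Literal("BRCA1")))
        after = validate(graph, shape, profile=gene_profile)
        assert len(after.violations) <= len(before.violations)
        assert len(after.warnings) <= len(before.warnings)


class TestHumanize:
    def test_messages_phrase_requirements_and_improvements(self, gene_profile):
        graph = make_gene_entity_graph(properties=("identifier",))
        report = validate(graph, generate_shape(gene_profile),
                          profile=gene_profile)
        messages = humanize(report)
        must = [m for m in messages if "must be" in m]
        should = [m for m in messages if "should be" in m]
        assert len(must) == 1 and "schema:name" in must[0]
        assert len(should) == 2
        assert all("must be" not in m for m in should)

    def test_empty_report_gives_no_messages(self, gene_profile):
        graph = make_gene_entity_graph(
            properties=("identifier", "name", "description", "url"))
        report = validate(graph, generate_shape(gene_profile),
                          profile=gene_profile)
        assert humanize(report) == []
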
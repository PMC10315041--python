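"""Metric engine: generated ASK queries, per-metric semantics, the factory
registry, and the monotonicity/determinism invariants."""

import pytest
from hypothesis import given, settings, strategies as st
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from fairchecker import fixtures, harvest
from fairchecker.errors import ContractError
from fairchecker.metrics import (ACCESSIBILITY_PROPERTIES, CANONICAL_DEFINITIONS,
                                 LICENSE_PROPERTIES, METRIC_IDS,
                                 PROVENANCE_PROPERTIES, EvaluationConfig,
                                 MetricResult, build_values_ask,
                                 check_identifier_scheme, evaluate_all,
                                 evaluate_property_metric, metric_registry)
from fairchecker.namespaces import DCT, PAV, PROV, SCHEMA

SEED = 20240901

_IRI_POOL = tuple(str(p) for p in (
    SCHEMA.name, SCHEMA.license, SCHEMA.author, DCT.license, DCT.creator,
    PROV.wasGeneratedBy, PAV.authoredBy, SCHEMA.url, DCT.title,
    "http://example.org/vocab#p1", "http://example.org/vocab#p2",
))

_KNOWN_POOL = tuple(p for p in _IRI_POOL if not p.startswith("http://example.org/"))


def _triples_from(pool):
    return st.tuples(
        st.sampled_from([f"http://x.org/s{i}" for i in range(5)]),
        st.sampled_from(pool),
        st.sampled_from([f"http://x.org/o{i}" for i in range(3)]
                        + ["lit-a", "lit-b"]),
    )


triples = _triples_from(_IRI_POOL)
known_triples = _triples_from(_KNOWN_POOL)


def _graph_of(triple_list):
    graph = Graph()
    for s, p, o in triple_list:
        obj = URIRef(o) if o.startswith("http") else Literal(o)
        graph.add((URIRef(s), URIRef(p), obj))
    return graph


class TestBuildValuesAsk:
    def test_contains_values_clause_with_exact_properties(self):
        query = build_values_ask([str(SCHEMA.license), str(DCT.license)])
        assert "VALUES ?p" in query
        assert f"<{SCHEMA.license}>" in query and f"<{DCT.license}>" in query

    def test_license_query_matches_dct_license_triple(self):
        graph = _graph_of([("http://x.org/s0", str(DCT.license), "MIT")])
        assert bool(graph.query(build_values_ask(
            [str(SCHEMA.license), str(DCT.license)])))

    def test_false_on_empty_graph(self):
        assert not bool(Graph().query(build_values_ask([str(SCHEMA.license)])))

    def test_empty_list_rejected(self):
        with pytest.raises(ContractError):
            build_values_ask([])

    def test_relative_property_rejected(self):
        with pytest.raises(ContractError):
            build_values_ask(["license"])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(triples, max_size=50),
           st.lists(st.sampled_from(_IRI_POOL), min_size=1, max_size=6))
    def test_ask_equals_linear_scan_oracle(self, triple_list, prop_list):
        """The generated ASK answer equals the existential linear scan."""
        graph = _graph_of(triple_list)
        expected = any(str(p) in set(prop_list) for _, p, _ in graph)
        assert bool(graph.query(build_values_ask(prop_list))) == expected


class TestPropertyMetrics:
    def _resource(self, graph):
        return harvest.make_resource("http://x.org/page", graph)

    def _definition(self, metric_id):
        return next(d for d in CANONICAL_DEFINITIONS if d.id == metric_id)

    def test_license_triple_passes_r11_with_one_evidence(self):
        graph = _graph_of([("http://x.org/s0", str(SCHEMA.license), "MIT")])
        result = evaluate_property_metric(self._resource(graph),
                                          self._definition("R1.1"))
        assert result.status == "pass" and len(result.evidence) == 1

    def test_unrelated_property_fails_r11(self):
        graph = _graph_of([("http://x.org/s0", str(SCHEMA.name), "x")])
        result = evaluate_property_metric(self._resource(graph),
                                          self._definition("R1.1"))
        assert result.status == "fail" and result.evidence == []

    def test_two_provenance_triples_give_two_evidence_rows(self):
        graph = _graph_of([
            ("http://x.org/s0", str(PROV.wasGeneratedBy), "http://x.org/o0"),
            ("http://x.org/s0", str(PAV.authoredBy), "http://x.org/o1"),
        ])
        result = evaluate_property_metric(self._resource(graph),
                                          self._definition("R1.2"))
        assert result.status == "pass" and len(result.evidence) == 2

    def test_target_lists_match_shipped_vocabulary_tables(self):
        assert str(SCHEMA.license) in LICENSE_PROPERTIES
        assert str(DCT.creator) in PROVENANCE_PROPERTIES
        assert str(SCHEMA.downloadUrl) in ACCESSIBILITY_PROPERTIES


class TestIdentifierScheme:
    @pytest.mark.parametrize("identifier,expected", [
        ("https://doi.org/10.1186/s13326-023-00289-5", True),
        ("doi:10.1186/s13326-023-00289-5", True),
        ("10.1186/s13326-023-00289-5", True),
        ("https://identifiers.org/uniprot:P12345", True),
        ("http://purl.obolibrary.org/obo/GO_0008150", True),
        ("https://w3id.org/fair/principles", True),
        ("https://example.org/tools/phyml", False),
        ("not a uri", False),
        ("", False),
    ])
    def test_persistent_scheme_rules(self, identifier, expected):
        assert check_identifier_scheme(identifier) is expected


class TestMetricSemantics:
    def test_i3_ignores_rdf_type_and_same_authority_objects(self):
        graph = Graph()
        s = URIRef("http://x.org/page")
        graph.add((s, RDF.type, SCHEMA.Dataset))               # excluded: type
        graph.add((s, SCHEMA.url, URIRef("http://x.org/page#frag")))  # same host
        resource = harvest.make_resource(str(s), graph)
        results = {r.metric_id: r for r in evaluate_all(resource)}
        assert results["I3"].status == "fail"
        graph.add((s, SCHEMA.sameAs, URIRef("https://other.example.net/e")))
        results = {r.metric_id: r for r in evaluate_all(resource)}
        assert results["I3"].status == "pass"

    def test_i2_fails_when_any_namespace_is_unregistered(self):
        graph = _graph_of([("http://x.org/s0", str(SCHEMA.name), "x")])
        resource = harvest.make_resource("http://x.org/page", graph)
        assert {r.metric_id: r.status for r in evaluate_all(resource)}["I2"] == "pass"
        graph.add((URIRef("http://x.org/s0"),
                   URIRef("http://unregistered.example/ns#p"), Literal("y")))
        assert {r.metric_id: r.status for r in evaluate_all(resource)}["I2"] == "fail"

    def test_f1b_accepts_identifier_property_or_persistent_url(self):
        empty = Graph()
        with_id = _graph_of([("http://x.org/s0", str(SCHEMA.identifier), "id:1")])
        plain = harvest.make_resource("http://x.org/page", empty)
        persistent = harvest.make_resource("https://doi.org/10.1/abc", empty)
        annotated = harvest.make_resource("http://x.org/page", with_id)
        status = lambda res: {r.metric_id: r.status for r in evaluate_all(res)}["F1B"]
        assert status(plain) == "fail"
        assert status(persistent) == "pass"
        assert status(annotated) == "pass"

    def test_all_metrics_fail_on_empty_graph_and_unresolvable_url(self):
        resource = harvest.AnnotatedResource(
            subject_url="http://unreachable.invalid/x", graph=Graph(),
            retrieval_error="no route to host")
        statuses = [r.status for r in evaluate_all(resource)]
        # F1A still passes (the URL is syntactically a valid absolute URI);
        # every retrievability/content metric fails
        by_id = dict(zip(METRIC_IDS, statuses))
        assert by_id["A1.1"] == "fail" and by_id["F2A"] == "fail"
        assert sum(s == "pass" for s in statuses) == 1

    def test_r13_profile_conformance_fallback(self):
        """Without domain-registry terms, R1.3 can still pass when the
        entity conforms to a community profile with zero violations —
        but only when candidate profiles are configured."""
        from fairchecker import fixtures
        spec = fixtures.gene_profile()
        graph = fixtures.make_gene_entity_graph(properties=("identifier", "name"))
        resource = harvest.make_resource("http://x.org/gene-page", graph)
        default = {r.metric_id: r.status for r in evaluate_all(resource)}
        assert default["R1.3"] == "fail"
        config = EvaluationConfig(profile_specs=(spec,))
        with_profiles = {r.metric_id: r.status
                         for r in evaluate_all(resource, config)}
        assert with_profiles["R1.3"] == "pass"
        # a non-conformant entity does not pass via the fallback
        partial = fixtures.make_gene_entity_graph(properties=("identifier",))
        partial_res = harvest.make_resource("http://x.org/gene-page", partial)
        assert {r.metric_id: r.status
                for r in evaluate_all(partial_res, config)}["R1.3"] == "fail"

    def test_failing_metric_carries_recommendation(self):
        resource = harvest.make_resource("http://x.org/page", Graph())
        results = {r.metric_id: r for r in evaluate_all(resource)}
        assert "license" in results["R1.1"].recommendation
        assert results["F1A"].recommendation == ""


class TestRegistry:
    def test_canonical_registry_has_exactly_the_twelve_ids(self):
        registry = metric_registry()
        assert [d.id for d in registry.definitions()] == list(METRIC_IDS)

    def test_alternative_implementation_selected_for_one_metric_only(self):
        registry = metric_registry()

        def strict_r11(resource, config):
            return MetricResult("R1.1", "fail", log="strict: never passes")

        registry.register("R1.1", "strict", strict_r11)
        registry.select("R1.1", "strict")
        graph = _graph_of([("http://x.org/s0", str(SCHEMA.license), "MIT")])
        resource = harvest.make_resource("http://x.org/page", graph)
        results = {r.metric_id: r for r in
                   evaluate_all(resource, registry=registry)}
        assert results["R1.1"].status == "fail"          # strict variant used
        assert results["F2A"].status == "pass"           # others untouched

    def test_unknown_metric_id_rejected(self):
        registry = metric_registry()
        with pytest.raises(ContractError):
            registry.register("F9", "alt", lambda r, c: None)


class TestEvaluateAllInvariants:
    def test_results_in_canonical_order(self):
        resource = harvest.make_resource("http://x.org/page", Graph())
        assert [r.metric_id for r in evaluate_all(resource)] == list(METRIC_IDS)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(known_triples, max_size=20),
           st.lists(known_triples, min_size=1, max_size=5))
    def test_monotonicity_under_known_vocabulary_additions(self, base, extra):
        """Adding triples never flips a metric pass->fail (the predicate
        pool uses registered vocabularies, so the universal I2 check is
        monotone here too)."""
        resource = harvest.make_resource("http://x.org/page", _graph_of(base))
        before = [r.status == "pass" for r in evaluate_all(resource)]
        for triple in _graph_of(extra):
            resource.graph.add(triple)
        after = [r.status == "pass" for r in evaluate_all(resource)]
        assert all(not (b and not a) for b, a in zip(before, after))

    def test_i2_is_the_only_metric_sensitive_to_unregistered_additions(self):
        """Arbitrary additions keep every existential metric monotone; the
        universal vocabulary check I2 alone may flip on an unregistered
        namespace."""
        graph = _graph_of([("http://x.org/s0", str(SCHEMA.name), "x")])
        resource = harvest.make_resource("http://x.org/page", graph)
        before = {r.metric_id: r.status for r in evaluate_all(resource)}
        graph.add((URIRef("http://x.org/s0"),
                   URIRef("http://unregistered.example/ns#p"), Literal("y")))
        after = {r.metric_id: r.status for r in evaluate_all(resource)}
        flipped = [m for m in METRIC_IDS
                   if before[m] == "pass" and after[m] == "fail"]
        assert flipped == ["I2"]

    def test_offline_runs_are_deterministic(self, server):
        url = server.url_for("/tool.html")
        first = harvest.harvest_url(url)
        second = harvest.harvest_url(url)
        as_rows = lambda res: [(r.metric_id, r.status, r.evidence, r.recommendation)
                               for r in evaluate_all(res)]
        assert as_rows(first) == as_rows(second)


class TestWorkedExamples:
    def test_bare_page_passes_exactly_f1a_and_a11(self, server):
        resource = harvest.harvest_url(server.url_for("/bare.html"))
        passed = {r.metric_id for r in evaluate_all(resource)
                  if r.status == "pass"}
        assert passed == {"F1A", "A1.1"}

    def test_annotated_tool_page_fails_exactly_license_and_provenance(self, server):
        resource = harvest.harvest_url(server.url_for("/tool.html"))
        failed = {r.metric_id for r in evaluate_all(resource)
                  if r.status != "pass"}
        assert failed == {"R1.1", "R1.2"}

    def test_adding_license_group_also_validates_r11(self, server):
        resource = harvest.harvest_url(server.url_for("/tool-licensed.html"))
        failed = {r.metric_id for r in evaluate_all(resource)
                  if r.status != "pass"}
        assert failed == {"R1.2"}
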
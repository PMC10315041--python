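"""The FAIR metric engine.

Twelve maturity indicators are evaluated per resource: F1A, F1B, F2A, F2B
(Findability), A1.1, A1.2 (Accessibility), I1, I2, I3 (Interoperability)
and R1.1, R1.2, R1.3 (Reusability). Long-term preservation (A2) and F3 are
deliberately not assessed: neither has a workable Semantic Web test.

Property-presence metrics are operationalized as generated SPARQL ASK
queries whose VALUES clause enumerates the metric's target properties; the
query answers true when at least one target property occurs as a predicate
in the resource graph. The remaining metrics test the identifier, the
retrieval protocol, the graph structure, or vocabulary-registry membership.

A factory-style registry allows alternative implementations of a metric to
be registered and selected by name, defaulting to the canonical one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from urllib.parse import urlparse

from rdflib import Graph, URIRef
from rdflib.namespace import RDF

from . import vocab
from .errors import ContractError
from .harvest import AnnotatedResource, is_absolute_uri
from .namespaces import CC, DBO, DCAT, DCT, DOAP, NIE, ODRL, PAV, PROV, SCHEMA, STO, XHV
from .recommendations import recommendation_for

METRIC_IDS: tuple[str, ...] = (
    "F1A", "F1B", "F2A", "F2B", "A1.1", "A1.2",
    "I1", "I2", "I3", "R1.1", "R1.2", "R1.3",
)

OPEN_PROTOCOL_SCHEMES = frozenset({"http", "https", "ftp"})

#: identifier/title properties signalling findable metadata (F1B).
FINDABILITY_PROPERTIES: tuple[str, ...] = tuple(str(p) for p in (
    DCT.identifier, SCHEMA.identifier, DCT.title, DCT.description,
))

#: access-policy / access-point properties (A1.2). schema:downloadUrl is
#: included alongside the DCAT access properties: a direct download link is
#: the access declaration software pages actually carry.
ACCESSIBILITY_PROPERTIES: tuple[str, ...] = tuple(str(p) for p in (
    ODRL.hasPolicy, DCT.rights, DCT.accessRights,
    DCAT.accessURL, DCAT.downloadURL, DCAT.endpointDescription,
    DCAT.endpointURL, SCHEMA.downloadUrl,
))

#: machine-readable license properties (R1.1).
LICENSE_PROPERTIES: tuple[str, ...] = tuple(str(p) for p in (
    SCHEMA.license, DCT.license, DOAP.license, DBO.license,
    CC.license, XHV.license, STO.license, NIE.license,
))

#: provenance properties from PROV, PAV, DC-Terms and Schema.org (R1.2).
PROVENANCE_PROPERTIES: tuple[str, ...] = tuple(str(p) for p in (
    PROV.wasGeneratedBy, PROV.wasDerivedFrom, PROV.wasAttributedTo,
    PROV.used, PROV.wasInformedBy, PROV.wasAssociatedWith,
    PROV.startedAtTime, PROV.endedAtTime,
    DCT.hasVersion, DCT.isVersionOf, DCT.creator, DCT.contributor,
    DCT.publisher,
    PAV.hasVersion, PAV.version, PAV.hasCurrentVersion, PAV.createdBy,
    PAV.authoredBy, PAV.retrievedFrom, PAV.importedFrom, PAV.createdWith,
    PAV.retrievedBy, PAV.importedBy, PAV.curatedBy, PAV.createdAt,
    PAV.previousVersion,
    SCHEMA.creator, SCHEMA.author, SCHEMA.publisher, SCHEMA.provider,
    SCHEMA.funder,
))

_PERSISTENT_HOSTS = frozenset({
    "doi.org", "dx.doi.org", "www.doi.org",
    "identifiers.org", "www.identifiers.org",
    "w3id.org", "www.w3id.org",
})


@dataclass(frozen=True)
class MetricDefinition:
    """Identity and test semantics of one FAIR maturity indicator."""

    id: str
    principle_text: str
    priority: str  # "essential" | "important" | "useful"
    test_kind: str  # property_presence | protocol | structure | registry | reference
    target_properties: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.id not in METRIC_IDS:
            raise ContractError(f"unknown metric id {self.id!r}")
        if self.test_kind == "property_presence" and not self.target_properties:
            raise ContractError(
                f"property_presence metric {self.id} needs target properties")


@dataclass
class MetricResult:
    """Outcome of one metric on one resource, with evidence and guidance."""

    metric_id: str
    status: str  # "pass" | "fail" | "error"
    evidence: list[str] = field(default_factory=list)
    recommendation: str = ""
    links: tuple[str, ...] = ()
    log: str = ""


CANONICAL_DEFINITIONS: tuple[MetricDefinition, ...] = (
    MetricDefinition("F1A", "(Meta)data are assigned a globally unique identifier",
                     "essential", "structure"),
    MetricDefinition("F1B", "(Meta)data are assigned a persistent identifier",
                     "essential", "property_presence", FINDABILITY_PROPERTIES),
    MetricDefinition("F2A", "Data are described with structured metadata",
                     "essential", "structure"),
    MetricDefinition("F2B", "Data are described with metadata populated using "
                            "shared vocabularies", "essential", "registry"),
    MetricDefinition("A1.1", "(Meta)data are retrievable by their identifier "
                             "using a standardised communication protocol: "
                             "open, free, and universally implementable",
                     "important", "protocol"),
    MetricDefinition("A1.2", "(Meta)data are retrievable through a clearly "
                             "declared access procedure or policy",
                     "important", "property_presence", ACCESSIBILITY_PROPERTIES),
    MetricDefinition("I1", "(Meta)data use a formal, accessible, shared, and "
                           "broadly applicable language for knowledge "
                           "representation", "important", "structure"),
    MetricDefinition("I2", "(Meta)data use vocabularies that follow FAIR "
                           "principles", "important", "registry"),
    MetricDefinition("I3", "(Meta)data include qualified references to other "
                           "(meta)data", "useful", "reference"),
    MetricDefinition("R1.1", "(Meta)data are released with a clear and "
                             "accessible data usage license",
                     "essential", "property_presence", LICENSE_PROPERTIES),
    MetricDefinition("R1.2", "(Meta)data are associated with detailed "
                             "provenance", "important", "property_presence",
                     PROVENANCE_PROPERTIES),
    MetricDefinition("R1.3", "(Meta)data meet domain-relevant community "
                             "standards", "essential", "registry"),
)


@dataclass
class EvaluationConfig:
    """Evaluation-time configuration.

    Offline by default: registry lookups go to the shipped fixture catalogs
    and no knowledge-graph enrichment runs unless endpoint profiles and a
    transport are supplied with ``enrich=True``.
    """

    catalogs: list = field(default_factory=vocab.default_catalogs)
    profile_specs: tuple = ()  # ProfileSpec candidates for the R1.3 fallback
    enrich: bool = False
    endpoint_profiles: tuple = ()
    transport: object | None = None


# ---------------------------------------------------------------------------
# Query generation and generic property-presence evaluation
# ---------------------------------------------------------------------------

def build_values_ask(target_properties: list[str] | tuple[str, ...]) -> str:
    """Generate the SPARQL ASK query testing presence of any target property.

    The VALUES clause enumerates exactly the given property IRIs bound to
    the predicate position; the query answers true iff some triple's
    predicate is among them.
    """
    if not target_properties:
        raise ContractError("target property list must be non-empty")
    for prop in target_properties:
        if not is_absolute_uri(str(prop)):
            raise ContractError(f"target property {prop!r} is not an absolute IRI")
    values = " ".join(f"<{p}>" for p in target_properties)
    return (
        "ASK {\n"
        f"    VALUES ?p {{ {values} }}\n"
        "    ?s ?p ?o .\n"
        "}"
    )


def _matching_triples(graph: Graph, properties: tuple[str, ...]) -> list[str]:
    rows = []
    prop_set = {URIRef(p) for p in properties}
    for s, p, o in graph:
        if p in prop_set:
            rows.append(f"{s.n3()} {p.n3()} {o.n3()} .")
    return sorted(rows)


def evaluate_property_metric(resource: AnnotatedResource,
                             metric: MetricDefinition) -> MetricResult:
    """Evaluate a property-presence metric via its generated ASK query.

    The verdict comes from executing the ASK query on the resource graph;
    the evidence lists every triple whose predicate is a target property.
    """
    if metric.test_kind != "property_presence":
        raise ContractError(f"{metric.id} is not a property_presence metric")
    query = build_values_ask(metric.target_properties)
    try:
        answer = bool(resource.graph.query(query))
    except Exception as exc:
        return _finish(MetricResult(metric.id, "error", log=str(exc)))
    evidence = _matching_triples(resource.graph, metric.target_properties) \
        if answer else []
    return _finish(MetricResult(metric.id, "pass" if answer else "fail",
                                evidence=evidence,
                                log=f"ASK answered {str(answer).lower()}"))


def check_identifier_scheme(identifier: str) -> bool:
    """True iff the identifier uses a recognised persistent scheme:
    a DOI (``10.`` prefix, ``doi:`` or a doi.org URL), Identifiers.org,
    purl.* or w3id.org. Unparseable strings are simply not persistent."""
    if not identifier:
        return False
    text = identifier.strip()
    lowered = text.lower()
    if lowered.startswith("doi:"):
        return True
    if lowered.startswith("10.") and "/" in lowered:
        return True
    try:
        parts = urlparse(text)
    except ValueError:
        return False
    host = parts.netloc.lower().rsplit("@", 1)[-1].split(":")[0]
    if host in _PERSISTENT_HOSTS:
        return True
    if host.startswith("purl."):
        return True
    return False


# ---------------------------------------------------------------------------
# Canonical per-metric evaluators
# ---------------------------------------------------------------------------

def _finish(result: MetricResult) -> MetricResult:
    text, links = recommendation_for(result.metric_id, result.status)
    result.recommendation = text
    result.links = links
    return result


def _eval_f1a(resource, config):
    ok = is_absolute_uri(resource.subject_url)
    evidence = [f"identifier {resource.subject_url} is an absolute URI"] if ok else []
    return _finish(MetricResult("F1A", "pass" if ok else "fail", evidence=evidence))


def _eval_f1b(resource, config):
    definition = _definition("F1B")
    prop_result = evaluate_property_metric(resource, definition)
    if prop_result.status == "pass":
        prop_result.log = "identifier property present; " + prop_result.log
        return prop_result
    if check_identifier_scheme(resource.subject_url):
        return _finish(MetricResult(
            "F1B", "pass",
            evidence=[f"resource URL {resource.subject_url} uses a "
                      "persistent-identifier scheme"],
            log="no identifier property; URL scheme is persistent"))
    return _finish(MetricResult("F1B", "fail",
                                log="no identifier property and the URL is not "
                                    "a recognised persistent identifier"))


def _eval_f2a(resource, config):
    n = len(resource.graph)
    if n:
        return _finish(MetricResult("F2A", "pass",
                                    evidence=[f"harvested graph holds {n} triples"]))
    return _finish(MetricResult("F2A", "fail", log="harvested graph is empty"))


def _eval_f2b(resource, config):
    classes, properties = vocab.used_terms(resource.graph)
    known = sorted(t for t in classes | properties
                   if not vocab.is_infrastructure(t)
                   and vocab.known_to_any(t, config.catalogs))
    if known:
        return _finish(MetricResult(
            "F2B", "pass",
            evidence=[f"term {t} is registered" for t in known]))
    return _finish(MetricResult("F2B", "fail",
                                log="no used term is known to any registry"))


def _eval_a11(resource, config):
    scheme = urlparse(resource.subject_url).scheme.lower()
    if scheme not in OPEN_PROTOCOL_SCHEMES:
        return _finish(MetricResult(
            "A1.1", "fail", log=f"scheme {scheme!r} is not an open standard protocol"))
    if resource.http_status is not None:
        if resource.http_status < 400:
            return _finish(MetricResult(
                "A1.1", "pass",
                evidence=[f"resolved over {scheme} with terminal status "
                          f"{resource.http_status}"]))
        return _finish(MetricResult(
            "A1.1", "fail",
            log=f"terminal HTTP status {resource.http_status}"))
    if resource.retrieval_error is not None:
        return _finish(MetricResult("A1.1", "fail",
                                    log=f"retrieval failed: {resource.retrieval_error}"))
    if resource.content_kind == "rdf_serialization":
        # batch dumps are never fetched; the protocol check degrades to the
        # identifier-scheme test
        return _finish(MetricResult(
            "A1.1", "pass",
            evidence=[f"identifier uses open protocol scheme {scheme}"]))
    return _finish(MetricResult("A1.1", "fail",
                                log="resource was not retrieved over a protocol"))


def _eval_i1(resource, config):
    if len(resource.graph) and resource.syntaxes_found:
        syntaxes = ", ".join(sorted(resource.syntaxes_found))
        return _finish(MetricResult(
            "I1", "pass",
            evidence=[f"{len(resource.graph)} RDF triples obtained from: {syntaxes}"]))
    return _finish(MetricResult("I1", "fail",
                                log="no triples from a standard RDF syntax"))


def _eval_i2(resource, config):
    if not len(resource.graph):
        return _finish(MetricResult("I2", "fail", log="empty graph"))
    classes, properties = vocab.used_terms(resource.graph)
    terms = sorted(t for t in classes | properties if not vocab.is_infrastructure(t))
    unknown = [t for t in terms if not vocab.known_to_any(t, config.catalogs)]
    if unknown:
        return _finish(MetricResult(
            "I2", "fail",
            log="namespaces unknown to every registry: "
                + ", ".join(sorted(unknown))))
    return _finish(MetricResult(
        "I2", "pass",
        evidence=[f"term {t} belongs to a registered vocabulary" for t in terms]))


def _eval_i3(resource, config):
    authority = urlparse(resource.subject_url).netloc.lower()
    evidence = []
    for s, p, o in resource.graph:
        if p == RDF.type or not isinstance(o, URIRef):
            continue
        if urlparse(str(o)).netloc.lower() != authority:
            evidence.append(f"{s.n3()} {p.n3()} {o.n3()} .")
    if evidence:
        return _finish(MetricResult("I3", "pass", evidence=sorted(evidence)))
    return _finish(MetricResult("I3", "fail",
                                log="no reference to an external authority"))


def _eval_r13(resource, config):
    classes, properties = vocab.used_terms(resource.graph)
    domain_known = sorted(t for t in classes | properties
                          if not vocab.is_infrastructure(t)
                          and vocab.known_to_any(t, config.catalogs, kind="domain"))
    if domain_known:
        return _finish(MetricResult(
            "R1.3", "pass",
            evidence=[f"term {t} is part of a domain community standard"
                      for t in domain_known]))
    if config.profile_specs:
        from . import profiles as profile_shacl
        for entity in sorted(set(resource.graph.subjects()), key=str):
            if not isinstance(entity, URIRef):
                continue
            spec = profile_shacl.select_profile(resource.graph, entity,
                                                list(config.profile_specs))
            if spec is None:
                continue
            shape = profile_shacl.generate_shape(spec)
            report = profile_shacl.validate(resource.graph, shape,
                                            profile=spec)
            if report.conforms:
                return _finish(MetricResult(
                    "R1.3", "pass",
                    evidence=[f"{entity} conforms to community profile "
                              f"{spec.name} with zero violations"]))
    return _finish(MetricResult("R1.3", "fail",
                                log="no domain-registry term and no conformant "
                                    "community profile"))


def _property_evaluator(metric_id):
    def _eval(resource, config):
        return evaluate_property_metric(resource, _definition(metric_id))
    return _eval


_CANONICAL_EVALUATORS = {
    "F1A": _eval_f1a,
    "F1B": _eval_f1b,
    "F2A": _eval_f2a,
    "F2B": _eval_f2b,
    "A1.1": _eval_a11,
    "A1.2": _property_evaluator("A1.2"),
    "I1": _eval_i1,
    "I2": _eval_i2,
    "I3": _eval_i3,
    "R1.1": _property_evaluator("R1.1"),
    "R1.2": _property_evaluator("R1.2"),
    "R1.3": _eval_r13,
}


def _definition(metric_id: str) -> MetricDefinition:
    for definition in CANONICAL_DEFINITIONS:
        if definition.id == metric_id:
            return definition
    raise ContractError(f"unknown metric id {metric_id!r}")


# ---------------------------------------------------------------------------
# Registry (factory) and whole-resource evaluation
# ---------------------------------------------------------------------------

class MetricRegistry:
    """Factory-style registry of metric implementations.

    Each canonical metric id maps to named implementations; ``canonical``
    is always present and selected by default. Alternative implementations
    (e.g. a stricter license test) register under the same id and are
    switched in with :meth:`select`.
    """

    def __init__(self) -> None:
        self._definitions = {d.id: d for d in CANONICAL_DEFINITIONS}
        self._implementations = {mid: {"canonical": ev}
                                 for mid, ev in _CANONICAL_EVALUATORS.items()}
        self._selected = {mid: "canonical" for mid in METRIC_IDS}

    def definitions(self) -> list[MetricDefinition]:
        return [self._definitions[mid] for mid in METRIC_IDS]

    def register(self, metric_id: str, name: str, evaluator,
                 definition: MetricDefinition | None = None) -> None:
        if metric_id not in self._implementations:
            raise ContractError(f"unknown metric id {metric_id!r}")
        self._implementations[metric_id][name] = evaluator
        if definition is not None:
            if definition.id != metric_id:
                raise ContractError("definition id does not match registration id")

    def select(self, metric_id: str, name: str) -> None:
        if metric_id not in self._implementations:
            raise ContractError(f"unknown metric id {metric_id!r}")
        if name not in self._implementations[metric_id]:
            raise ContractError(f"no implementation {name!r} for {metric_id}")
        self._selected[metric_id] = name

    def evaluator(self, metric_id: str):
        return self._implementations[metric_id][self._selected[metric_id]]


def metric_registry() -> MetricRegistry:
    """A fresh registry holding the canonical 12 metric definitions."""
    return MetricRegistry()


def evaluate_all(resource: AnnotatedResource,
                 config: EvaluationConfig | None = None,
                 registry: MetricRegistry | None = None) -> list[MetricResult]:
    """Evaluate all 12 metrics on a resource, in canonical order.

    When enrichment is enabled in the config it runs first, so retrieved
    triples count toward metric evidence. One metric's error never blocks
    the others. Deterministic for fixed inputs and offline backends.
    """
    config = config or EvaluationConfig()
    registry = registry or metric_registry()
    if config.enrich and config.endpoint_profiles and config.transport is not None:
        from .enrichment import enrich
        resource = enrich(resource, list(config.endpoint_profiles),
                          config.transport)
    results = []
    for metric_id in METRIC_IDS:
        try:
            results.append(registry.evaluator(metric_id)(resource, config))
        except Exception as exc:  # isolate per-metric failures
            results.append(_finish(MetricResult(metric_id, "error", log=str(exc))))
    return results
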
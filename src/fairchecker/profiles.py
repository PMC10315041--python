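"""Community metadata profiles and their SHACL realisation.

A community *profile* (in the Bioschemas sense) says which properties an
entity of a given type should carry, bucketed by marginality: *minimum*
properties must be present, *recommended* properties should be, *optional*
properties are free. Profiles arrive as JSON-LD specification documents;
this module parses them, instantiates a single SHACL shape template per
profile (minimum -> ``sh:Violation`` severity, recommended ->
``sh:Warning``), selects the right profile for an entity, validates, and
renders the outcome as human-readable "must be" / "should be" messages.

Only presence (``sh:minCount 1``) is constrained: marginality, not
cardinality, is what the profiles standardise. Optional properties are
parsed but generate no constraint, since an Info-severity shape would
change the report semantics without adding guidance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from string import Template

from rdflib import Graph, URIRef
from rdflib.namespace import RDF

from .errors import ContractError, ProfileParseError
from .harvest import is_absolute_uri
from .namespaces import DCT, SCHEMA, SCHEMA_HTTPS, SH, prefixed

MARGINALITIES = ("minimum", "recommended", "optional")

#: type-IRI aliases applied when matching an entity's rdf:type to a
#: profile's target class (http/https Schema.org variants).
DEFAULT_CLASS_ALIASES: dict[str, str] = {
    str(SCHEMA_HTTPS): str(SCHEMA),
}


@dataclass(frozen=True)
class ProfileSpec:
    """A parsed community profile."""

    name: str
    source_url: str
    target_class: str
    minimum_properties: tuple[str, ...]
    recommended_properties: tuple[str, ...]
    optional_properties: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not is_absolute_uri(self.target_class):
            raise ProfileParseError(
                f"target class {self.target_class!r} is not an absolute IRI")
        overlap = set(self.minimum_properties) & set(self.recommended_properties)
        if overlap:
            raise ProfileParseError(
                "properties cannot be both minimum and recommended: "
                + ", ".join(sorted(overlap)))


def parse_profile(spec_document: str | dict) -> ProfileSpec:
    """Parse a machine-readable profile specification (JSON-LD dialect).

    The document must declare a target class and bucket each property under
    a known marginality label; an unknown label is a parse error naming it.
    """
    if isinstance(spec_document, str):
        try:
            document = json.loads(spec_document)
        except json.JSONDecodeError as exc:
            raise ProfileParseError(f"not valid JSON: {exc}") from exc
    else:
        document = spec_document
    if not isinstance(document, dict):
        raise ProfileParseError("profile document must be a JSON object")

    target_class = document.get("targetClass")
    if not target_class:
        raise ProfileParseError("profile document lacks a target class")
    name = document.get("name") or document.get("schema:name")
    if not name:
        raise ProfileParseError("profile document lacks a name")
    source_url = document.get("@id", "")

    buckets: dict[str, list[str]] = {m: [] for m in MARGINALITIES}
    for entry in document.get("properties", []):
        prop = entry.get("property")
        marginality = entry.get("marginality")
        if marginality not in MARGINALITIES:
            raise ProfileParseError(
                f"unknown marginality label {marginality!r} on {prop!r}")
        if not prop or not is_absolute_uri(prop):
            raise ProfileParseError(f"property {prop!r} is not an absolute IRI")
        buckets[marginality].append(prop)

    return ProfileSpec(name=name, source_url=source_url,
                       target_class=target_class,
                       minimum_properties=tuple(buckets["minimum"]),
                       recommended_properties=tuple(buckets["recommended"]),
                       optional_properties=tuple(buckets["optional"]))


def builtin_profiles() -> list[ProfileSpec]:
    """The frozen in-repo profiles (ComputationalTool, Gene)."""
    out = []
    for filename in ("computational_tool.jsonld", "gene.jsonld"):
        text = (resources.files("fairchecker") / "data" / "profiles" / filename
                ).read_text(encoding="utf-8")
        out.append(parse_profile(text))
    return out


# ---------------------------------------------------------------------------
# Shape generation: one maintained template, instantiated per profile
# ---------------------------------------------------------------------------

_SHAPE_TEMPLATE = Template("""\
@prefix sh: <http://www.w3.org/ns/shacl#> .

<$shape_iri>
    a sh:NodeShape ;
    sh:targetClass <$target_class> ;
$property_blocks
.
""")

_PROPERTY_BLOCK = Template("""\
    sh:property [
        sh:path <$path> ;
        sh:minCount 1 ;
        sh:severity sh:$severity ;
        sh:message "Property $label $verb provided" ;
    ] ;\
""")


def generate_shape_text(profile: ProfileSpec) -> str:
    """Instantiate the SHACL shape template for a profile.

    Output is bit-stable for a fixed profile: property shapes are emitted
    in sorted order within each marginality bucket, minimum first.
    """
    blocks = []
    for severity, verb, props in (
            ("Violation", "must be", profile.minimum_properties),
            ("Warning", "should be", profile.recommended_properties)):
        for prop in sorted(props):
            blocks.append(_PROPERTY_BLOCK.substitute(
                path=prop, severity=severity, label=prefixed(prop), verb=verb))
    shape_iri = (profile.source_url or f"urn:fairchecker:profile:{profile.name}") \
        + "#shape"
    return _SHAPE_TEMPLATE.substitute(shape_iri=shape_iri,
                                      target_class=profile.target_class,
                                      property_blocks="\n".join(blocks))


def generate_shape(profile: ProfileSpec) -> Graph:
    """The profile's SHACL shape as an RDF graph."""
    graph = Graph()
    graph.parse(data=generate_shape_text(profile), format="turtle")
    return graph


# ---------------------------------------------------------------------------
# Profile selection
# ---------------------------------------------------------------------------

def _canonical_class(iri: str, aliases: dict[str, str]) -> str:
    for alias_ns, canonical_ns in aliases.items():
        if iri.startswith(alias_ns):
            return canonical_ns + iri[len(alias_ns):]
    return iri


def select_profile(entity_graph: Graph, entity: URIRef | str,
                   available: list[ProfileSpec],
                   aliases: dict[str, str] | None = None) -> ProfileSpec | None:
    """Choose the profile to validate *entity* against.

    A provider-declared ``dct:conformsTo`` pointing at a known profile URL
    wins; otherwise the entity's ``rdf:type`` is matched against profile
    target classes (modulo configured aliases). Ties break toward the
    profile with more minimum properties already present, then the
    lexicographically smaller name. ``None`` when nothing applies.
    """
    aliases = DEFAULT_CLASS_ALIASES if aliases is None else aliases
    node = URIRef(entity) if not isinstance(entity, URIRef) else entity

    declared = {str(o) for o in entity_graph.objects(node, DCT.conformsTo)}
    for spec in available:
        if spec.source_url and spec.source_url in declared:
            return spec

    types = {_canonical_class(str(o), aliases)
             for o in entity_graph.objects(node, RDF.type)}
    candidates = [spec for spec in available
                  if _canonical_class(spec.target_class, aliases) in types]
    if not candidates:
        return None

    def present_minimums(spec: ProfileSpec) -> int:
        return sum(1 for p in spec.minimum_properties
                   if (node, URIRef(p), None) in entity_graph)

    return sorted(candidates,
                  key=lambda s: (-present_minimums(s), s.name))[0]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FocusResult:
    entity: str
    violations: tuple[str, ...]  # missing minimum-property IRIs
    warnings: tuple[str, ...]    # missing recommended-property IRIs


@dataclass(frozen=True)
class ShapeReport:
    """Outcome of validating a graph against one generated shape."""

    profile_name: str
    focus_results: tuple[FocusResult, ...]

    @property
    def conforms(self) -> bool:
        return all(not f.violations for f in self.focus_results)

    @property
    def violations(self) -> tuple[tuple[str, str], ...]:
        return tuple((f.entity, p) for f in self.focus_results
                     for p in f.violations)

    @property
    def warnings(self) -> tuple[tuple[str, str], ...]:
        return tuple((f.entity, p) for f in self.focus_results
                     for p in f.warnings)


def validate(graph: Graph, shape: Graph,
             profile: ProfileSpec | None = None) -> ShapeReport:
    """Validate *graph* against a generated shape.

    Interprets the presence-constraint subset this package generates
    (``sh:targetClass`` node shapes with ``sh:path`` / ``sh:minCount 1`` /
    ``sh:severity`` property shapes): a focus entity violates a
    Violation-severity shape when it has zero occurrences of the path
    property, and accrues a warning likewise for Warning severity.
    Deterministic: foci and properties are reported in sorted order.
    """
    node_shapes = list(shape.subjects(RDF.type, SH.NodeShape))
    if not node_shapes:
        raise ContractError("shape graph contains no sh:NodeShape")

    focus_map: dict[str, dict[str, list[str]]] = {}
    for node_shape in node_shapes:
        target_class = shape.value(node_shape, SH.targetClass)
        if target_class is None:
            raise ContractError("node shape lacks sh:targetClass")
        constraints = []
        for prop_shape in shape.objects(node_shape, SH.property):
            path = shape.value(prop_shape, SH.path)
            if path is None:
                raise ContractError("property shape lacks sh:path")
            severity = shape.value(prop_shape, SH.severity) or SH.Violation
            constraints.append((str(path), severity))
        for focus in sorted(graph.subjects(RDF.type, target_class), key=str):
            slot = focus_map.setdefault(str(focus),
                                        {"violations": [], "warnings": []})
            for path, severity in constraints:
                if (focus, URIRef(path), None) in graph:
                    continue
                if severity == SH.Warning:
                    slot["warnings"].append(path)
                else:
                    slot["violations"].append(path)

    results = tuple(
        FocusResult(entity=entity,
                    violations=tuple(sorted(set(slots["violations"]))),
                    warnings=tuple(sorted(set(slots["warnings"]))))
        for entity, slots in sorted(focus_map.items()))
    name = profile.name if profile is not None else ""
    return ShapeReport(profile_name=name, focus_results=results)


def humanize(report: ShapeReport) -> list[str]:
    """Render a shape report as readable requirement/improvement messages.

    Missing minimum properties read as requirements ("must be"); missing
    recommended properties read as improvements ("should be").
    """
    messages = []
    for focus in report.focus_results:
        for prop in focus.violations:
            messages.append(
                f"Property {prefixed(prop)} must be provided for <{focus.entity}>")
        for prop in focus.warnings:
            messages.append(
                f"Property {prefixed(prop)} should be provided for <{focus.entity}>")
    return messages
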
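"""Synthetic fixtures with fully known ground truth.

Everything the assessment pipeline consumes can be generated here with no
network access: HTML pages embedding annotations in any of the three
syntaxes, profile specification documents, and batch RDF dumps whose
per-resource metric vectors are prescribed and recorded in a ledger. The
generators are seed-deterministic and byte-stable, so round-trip laws
(extraction of a generated page equals its triple set; a prescribed batch
reproduces its combination counts exactly) can be asserted as equalities.

The worked-example pages emulate the two ends of the software-sharing
story: a plain HTML landing page with no embedded metadata, and the same
page after annotation with the ComputationalTool community profile plus
EDAM ontology terms.
"""

from __future__ import annotations

import html as html_escape
import http.server
import json
import random
import threading
from dataclasses import dataclass, field

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from .errors import ContractError, ProfileParseError
from .metrics import METRIC_IDS
from .namespaces import DCT, EDAM, SCHEMA
from .profiles import ProfileSpec, builtin_profiles, parse_profile

SYNTAXES = ("json-ld", "rdfa", "microdata")

GROUPS = ("rdf_type", "findability_ids", "accessibility", "license",
          "provenance", "profile_minimum", "profile_recommended",
          "edam_terms")

#: metrics a batch prescription may toggle; the rest are structurally true
#: for dump resources (absolute-IRI subjects, non-empty native-RDF graphs
#: built from registered vocabularies).
TOGGLEABLE_METRICS = ("F1B", "A1.1", "A1.2", "I2", "I3",
                      "R1.1", "R1.2", "R1.3")
FIXED_TRUE_METRICS = tuple(m for m in METRIC_IDS if m not in TOGGLEABLE_METRICS)

#: default per-metric pass probabilities for sampled batches, shaped like a
#: large software-registry dump: licenses are the common gap, provenance is
#: never exposed.
DEFAULT_PASS_PROBABILITIES: dict[str, float] = {
    "F1B": 0.9, "A1.1": 1.0, "A1.2": 0.85, "I2": 0.95,
    "I3": 0.7, "R1.1": 0.6, "R1.2": 0.0, "R1.3": 0.9,
}

_UNREGISTERED = "https://vocab.example.net/ns#"


def computational_tool_profile() -> ProfileSpec:
    for spec in builtin_profiles():
        if spec.name == "ComputationalTool":
            return spec
    raise RuntimeError("builtin ComputationalTool profile missing")


def gene_profile() -> ProfileSpec:
    for spec in builtin_profiles():
        if spec.name == "Gene":
            return spec
    raise RuntimeError("builtin Gene profile missing")


# ---------------------------------------------------------------------------
# Page recipes and rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PageRecipe:
    """What an annotated fixture page should assert."""

    syntax: str = "json-ld"
    include_groups: tuple[str, ...] = ()
    profile: ProfileSpec | None = None
    subject_url: str = "https://example.org/resource/1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.syntax not in SYNTAXES:
            raise ContractError(f"unknown syntax {self.syntax!r}")
        unknown = set(self.include_groups) - set(GROUPS)
        if unknown:
            raise ContractError(f"unknown groups: {sorted(unknown)}")


def _edam_triples(subject: URIRef) -> list[tuple]:
    # attachment properties deliberately avoid the profile's recommended
    # set so EDAM annotation never changes completeness bookkeeping
    topic = URIRef(str(subject) + "#edam-topic")
    operation = URIRef(str(subject) + "#edam-operation")
    return [
        (subject, SCHEMA.applicationSubCategory, topic),
        (topic, RDF.type, EDAM.topic_0084),
        (subject, SCHEMA.about, operation),
        (operation, RDF.type, EDAM.operation_0324),
    ]


def recipe_triples(recipe: PageRecipe) -> Graph:
    """The exact triple set a recipe implies (the round-trip ground truth)."""
    s = URIRef(recipe.subject_url)
    profile = recipe.profile or computational_tool_profile()
    graph = Graph()
    for group in recipe.include_groups:
        if group == "rdf_type":
            graph.add((s, RDF.type, URIRef(profile.target_class)))
        elif group == "findability_ids":
            graph.add((s, SCHEMA.identifier, Literal("example-registry:0001")))
        elif group == "accessibility":
            graph.add((s, DCT.accessRights, Literal("public")))
        elif group == "license":
            graph.add((s, SCHEMA.license, Literal("MIT License")))
        elif group == "provenance":
            graph.add((s, DCT.creator, Literal("Alice Example")))
        elif group == "profile_minimum":
            for prop in profile.minimum_properties:
                graph.add((s, URIRef(prop), Literal(_prop_value(prop))))
        elif group == "profile_recommended":
            for prop in profile.recommended_properties:
                graph.add((s, URIRef(prop), Literal(_prop_value(prop))))
        elif group == "edam_terms":
            for triple in _edam_triples(s):
                graph.add(triple)
    return graph


def _prop_value(prop: str) -> str:
    local = prop.rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    return f"{local} value"


def _jsonld_from_graph(graph: Graph) -> str:
    nodes: dict[str, dict] = {}
    for s, p, o in graph:
        node = nodes.setdefault(str(s), {"@id": str(s)})
        if p == RDF.type:
            node.setdefault("@type", []).append(str(o))
            continue
        if isinstance(o, URIRef):
            value = {"@id": str(o)}
        else:
            value = str(o)
        node.setdefault(str(p), []).append(value)
    for node in nodes.values():
        if "@type" in node:
            node["@type"] = sorted(node["@type"])
        for key, values in node.items():
            if isinstance(values, list) and key != "@type":
                node[key] = sorted(values, key=json.dumps)
    payload = [nodes[k] for k in sorted(nodes)]
    return json.dumps(payload, indent=2, sort_keys=True)


def _rdfa_from_graph(graph: Graph) -> str:
    parts = []
    subjects = sorted({s for s, _, _ in graph}, key=str)
    for s in subjects:
        types = sorted(str(o) for o in graph.objects(s, RDF.type))
        typeof = f' typeof="{html_escape.escape(" ".join(types))}"' if types else ""
        parts.append(f'  <div about="{html_escape.escape(str(s))}"{typeof}>')
        for _, p, o in sorted(graph.triples((s, None, None)), key=str):
            if p == RDF.type:
                continue
            p_attr = html_escape.escape(str(p), quote=True)
            if isinstance(o, URIRef):
                parts.append(f'    <span property="{p_attr}" '
                             f'resource="{html_escape.escape(str(o), quote=True)}"></span>')
            else:
                parts.append(f'    <span property="{p_attr}" '
                             f'content="{html_escape.escape(str(o), quote=True)}"></span>')
        parts.append("  </div>")
    return "\n".join(parts)


def _microdata_from_graph(graph: Graph) -> str:
    parts = []
    subjects = sorted({s for s, _, _ in graph}, key=str)
    nested = {o for _, p, o in graph if p != RDF.type and isinstance(o, URIRef)
              and o in subjects}
    for s in subjects:
        if s in nested:
            continue  # rendered inline below its parent
        parts.append(_microdata_item(graph, s, subjects, indent="  "))
    return "\n".join(parts)


def _microdata_item(graph: Graph, s, subjects, indent: str) -> str:
    types = sorted(str(o) for o in graph.objects(s, RDF.type))
    itemtype = f' itemtype="{html_escape.escape(" ".join(types))}"' if types else ""
    lines = [f'{indent}<div itemscope itemid="{html_escape.escape(str(s))}"{itemtype}>']
    for _, p, o in sorted(graph.triples((s, None, None)), key=str):
        if p == RDF.type:
            continue
        p_attr = html_escape.escape(str(p), quote=True)
        if isinstance(o, URIRef) and o in subjects:
            inner = _microdata_item(graph, o, subjects, indent + "  ")
            inner = inner.replace("<div itemscope",
                                  f'<div itemprop="{p_attr}" itemscope', 1)
            lines.append(inner)
        elif isinstance(o, URIRef):
            lines.append(f'{indent}  <link itemprop="{p_attr}" '
                         f'href="{html_escape.escape(str(o), quote=True)}">')
        else:
            lines.append(f'{indent}  <meta itemprop="{p_attr}" '
                         f'content="{html_escape.escape(str(o), quote=True)}">')
    lines.append(f"{indent}</div>")
    return "\n".join(lines)


_PAGE_SHELL = """\
<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
{head}
</head>
<body>
<h1>{title}</h1>
<p>Synthetic fixture page.</p>
{body}
</body>
</html>
"""


def make_page(recipe: PageRecipe) -> str:
    """Render a recipe as an HTML page in the requested syntax."""
    graph = recipe_triples(recipe)
    head, body = "", ""
    if recipe.syntax == "json-ld":
        head = ('<script type="application/ld+json">\n'
                + _jsonld_from_graph(graph) + "\n</script>")
    elif recipe.syntax == "rdfa":
        body = _rdfa_from_graph(graph)
    else:
        body = _microdata_from_graph(graph)
    return _PAGE_SHELL.format(title="Fixture resource", head=head, body=body)


def make_bare_page() -> str:
    """A valid HTML page carrying zero extractable annotations."""
    return _PAGE_SHELL.format(title="A plain software landing page",
                              head="", body="<p>No embedded metadata here.</p>")


def make_computational_tool_page(include_license: bool = False,
                                 include_provenance: bool = False) -> str:
    """A software landing page annotated per the ComputationalTool profile.

    Embeds one JSON-LD block with every minimum and recommended profile
    property, a ``schema:identifier``, EDAM topic/operation terms typing
    the category/feature nodes, and a download link (the accessibility
    declaration). License and provenance statements are deliberately absent
    unless requested, so the default page passes every metric except the
    license and provenance ones.
    """
    doc = {
        "@context": {"@vocab": str(SCHEMA), "edam": str(EDAM)},
        "@id": "",
        "@type": "SoftwareApplication",
        "identifier": "biotools:phyml-like",
        "name": "PhyML-like phylogeny tool",
        "description": "Maximum-likelihood phylogenetic tree inference "
                       "from sequence alignments.",
        "url": {"@id": ""},
        "applicationCategory": "Phylogenetics",
        "applicationSubCategory": {"@id": "#edam-topic",
                                   "@type": "edam:topic_0084"},
        "citation": {"@id": "https://doi.org/10.1093/sysbio/syq010"},
        "downloadUrl": {"@id": "releases/tool.tar.gz"},
        "featureList": {"@id": "#edam-operation",
                        "@type": "edam:operation_0324"},
        "operatingSystem": "Linux",
        "softwareVersion": "3.3.20220408",
    }
    if include_license:
        doc["license"] = "https://opensource.org/licenses/MIT"
    if include_provenance:
        doc["author"] = {"@id": "#maintainer", "@type": "Person",
                         "name": "Alice Example"}
    head = ('<script type="application/ld+json">\n'
            + json.dumps(doc, indent=2, sort_keys=True) + "\n</script>")
    return _PAGE_SHELL.format(title="PhyML-like phylogeny tool", head=head,
                              body="<p>Download, documentation, citations.</p>")


def make_gene_entity_graph(subject_url: str = "https://example.org/gene/BRCA1",
                           properties: tuple[str, ...] = ("identifier", "name"),
                           ) -> Graph:
    """A Gene-typed entity carrying the named Schema.org properties."""
    graph = Graph()
    s = URIRef(subject_url)
    graph.add((s, RDF.type, SCHEMA.Gene))
    values = {"identifier": "HGNC:1100", "name": "BRCA1",
              "description": "BRCA1 DNA repair associated gene.",
              "url": "https://www.genenames.org/data/gene-symbol-report/#!/hgnc_id/HGNC:1100"}
    for prop in properties:
        graph.add((s, SCHEMA[prop], Literal(values[prop])))
    return graph


# ---------------------------------------------------------------------------
# Profile documents
# ---------------------------------------------------------------------------

def make_profile_document(name: str, target_class: str,
                          min_props: tuple[str, ...] | list[str],
                          rec_props: tuple[str, ...] | list[str],
                          optional_props: tuple[str, ...] | list[str] = (),
                          source_url: str | None = None) -> str:
    """A machine-readable profile specification that round-trips through
    :func:`fairchecker.profiles.parse_profile` exactly."""
    overlap = set(min_props) & set(rec_props)
    if overlap:
        raise ProfileParseError(
            "minimum and recommended sets overlap: " + ", ".join(sorted(overlap)))
    document = {
        "@context": {
            "schema": str(SCHEMA),
            "bsp": "https://bioschemas.org/profiles#",
            "name": "schema:name",
            "targetClass": {"@id": "bsp:targetClass", "@type": "@id"},
            "properties": "bsp:properties",
            "property": {"@id": "bsp:property", "@type": "@id"},
            "marginality": "bsp:marginality",
        },
        "@id": source_url or f"https://profiles.example.org/{name}/1.0",
        "@type": "bsp:Profile",
        "name": name,
        "targetClass": target_class,
        "properties": (
            [{"property": p, "marginality": "minimum"} for p in min_props]
            + [{"property": p, "marginality": "recommended"} for p in rec_props]
            + [{"property": p, "marginality": "optional"} for p in optional_props]
        ),
    }
    return json.dumps(document, indent=2)


# ---------------------------------------------------------------------------
# Batch dumps with a ground-truth ledger
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LedgerEntry:
    vector: dict[str, bool]
    recommended_k: int
    n_recommended: int


@dataclass
class BatchFixture:
    dump: str  # sorted N-Triples text (a valid Turtle subset)
    ledger: dict[str, LedgerEntry]
    profile: ProfileSpec = field(default_factory=computational_tool_profile)


def _normalize_vector(vector) -> dict[str, bool]:
    if isinstance(vector, dict):
        unknown = set(vector) - set(METRIC_IDS)
        if unknown:
            raise ContractError(f"unknown metric ids: {sorted(unknown)}")
        full = {m: True for m in METRIC_IDS}
        full.update({m: bool(v) for m, v in vector.items()})
    else:
        values = tuple(vector)
        if len(values) != len(METRIC_IDS):
            raise ContractError("metric vector must have 12 entries")
        full = dict(zip(METRIC_IDS, map(bool, values)))
    for metric in FIXED_TRUE_METRICS:
        if not full[metric]:
            raise ContractError(
                f"{metric} cannot be failed by a dump resource: subjects are "
                "absolute IRIs carrying non-empty native-RDF graphs built "
                "from registered vocabularies")
    return full


def _resource_triples(key: URIRef, vector: dict[str, bool], k: int,
                      profile: ProfileSpec) -> list[tuple]:
    s = key
    triples = [(s, RDF.type, URIRef(profile.target_class))]
    for prop in profile.minimum_properties:
        triples.append((s, URIRef(prop), Literal(_prop_value(prop))))
    recommended = sorted(profile.recommended_properties)
    download = str(SCHEMA.downloadUrl)
    pool = recommended if vector["A1.2"] else [p for p in recommended
                                               if p != download]
    if k > len(pool):
        raise ContractError(
            f"cannot include {k} recommended properties while failing A1.2 "
            "(the download link is itself an access declaration)")
    chosen = pool[:k]
    if vector["A1.2"] and k > 0 and download in recommended and download not in chosen:
        chosen = ([download] + [p for p in chosen if p != download])[:k]
    for prop in chosen:
        triples.append((s, URIRef(prop), Literal(_prop_value(prop))))
    if vector["A1.2"]:
        triples.append((s, DCT.accessRights, Literal("public")))
    if vector["F1B"]:
        triples.append((s, SCHEMA.identifier, Literal("example-registry:0001")))
    if not vector["I2"]:
        triples.append((s, URIRef(_UNREGISTERED + "customScore"), Literal("0.5")))
    if vector["I3"]:
        triples.append((s, SCHEMA.sameAs,
                        URIRef("https://registry.example.net/entry/"
                               + str(s).rsplit("/", 1)[-1].replace(":", "-"))))
    if vector["R1.1"]:
        triples.append((s, SCHEMA.license, Literal("MIT License")))
    if vector["R1.2"]:
        triples.append((s, DCT.creator, Literal("Alice Example")))
    if vector["R1.3"]:
        triples.extend(_edam_triples(s))
    return triples


def _nt_term(term) -> str:
    return term.n3()


def make_batch(n: int, vectors=None, pass_probabilities=None,
               recommended_counts=None, seed: int = 0) -> BatchFixture:
    """Generate an RDF dump of *n* resources with prescribed metric vectors.

    ``vectors`` may be a sequence of per-resource prescriptions (dicts over
    metric ids, or 12-tuples in canonical order) or a multiset mapping
    vector -> count; alternatively ``pass_probabilities`` samples each
    toggleable metric independently (seeded). ``recommended_counts``
    prescribes how many recommended ComputationalTool properties each
    resource carries (int, sequence, or None for seeded sampling).
    The dump is emitted as sorted N-Triples text, byte-identical for a
    fixed seed; the ledger records every resource's intended vector and
    recommended-property count.
    """
    if n < 0:
        raise ContractError("n must be >= 0")
    rng = random.Random(seed)
    profile = computational_tool_profile()

    if vectors is not None and pass_probabilities is not None:
        raise ContractError("give either vectors or pass_probabilities")
    if vectors is not None:
        if isinstance(vectors, dict):
            expanded = []
            for vector, count in sorted(vectors.items(), key=str):
                expanded.extend([vector] * count)
        else:
            expanded = list(vectors)
        if len(expanded) != n:
            raise ContractError(f"{len(expanded)} vectors for n={n} resources")
        prescriptions = [_normalize_vector(v) for v in expanded]
    else:
        probabilities = dict(DEFAULT_PASS_PROBABILITIES)
        if pass_probabilities:
            unknown = set(pass_probabilities) - set(METRIC_IDS)
            if unknown:
                raise ContractError(f"unknown metric ids: {sorted(unknown)}")
            for metric, p in pass_probabilities.items():
                if not 0.0 <= p <= 1.0:
                    raise ContractError(f"probability out of range for {metric}")
                if metric in FIXED_TRUE_METRICS and p != 1.0:
                    raise ContractError(
                        f"{metric} is structurally true for dump resources")
                if metric in TOGGLEABLE_METRICS:
                    probabilities[metric] = p
        prescriptions = []
        for _ in range(n):
            vector = {m: True for m in METRIC_IDS}
            for metric in TOGGLEABLE_METRICS:
                vector[metric] = rng.random() < probabilities[metric]
            prescriptions.append(vector)

    r = len(profile.recommended_properties)
    if recommended_counts is None:
        ks = [rng.randint(0, r - 1) for _ in range(n)]
    elif isinstance(recommended_counts, int):
        ks = [recommended_counts] * n
    else:
        ks = list(recommended_counts)
        if len(ks) != n:
            raise ContractError("recommended_counts length must equal n")

    triples: list[tuple] = []
    ledger: dict[str, LedgerEntry] = {}
    for i, (vector, k) in enumerate(zip(prescriptions, ks)):
        if vector["A1.1"]:
            key = URIRef(f"https://tools.example.org/entry/{i:05d}")
        else:
            key = URIRef(f"urn:example-registry:entry-{i:05d}")
        triples.extend(_resource_triples(key, vector, k, profile))
        ledger[str(key)] = LedgerEntry(vector=vector, recommended_k=k,
                                       n_recommended=r)

    lines = sorted(f"{_nt_term(s)} {_nt_term(p)} {_nt_term(o)} ."
                   for s, p, o in set(triples))
    return BatchFixture(dump="\n".join(lines) + ("\n" if lines else ""),
                        ledger=ledger, profile=profile)


# ---------------------------------------------------------------------------
# Ephemeral HTTP serving (protocol metrics exercised honestly)
# ---------------------------------------------------------------------------

class FixtureServer:
    """Serve fixture pages from memory on an ephemeral localhost port."""

    def __init__(self, pages: dict[str, str],
                 redirects: dict[str, str] | None = None) -> None:
        self._pages = {path if path.startswith("/") else "/" + path: body
                       for path, body in pages.items()}
        self._redirects = {path if path.startswith("/") else "/" + path: target
                           for path, target in (redirects or {}).items()}
        outer = self

        class Handler(http.server.BaseHTTPRequestHandler):
            def do_GET(self):  # noqa: N802  (http.server API)
                target = outer._redirects.get(self.path)
                if target is not None:
                    self.send_response(302)
                    self.send_header("Location", target)
                    self.end_headers()
                    return
                body = outer._pages.get(self.path)
                if body is None:
                    self.send_response(404)
                    self.send_header("Content-Type", "text/html")
                    self.end_headers()
                    self.wfile.write(b"<html><body>not found</body></html>")
                    return
                payload = body.encode("utf-8")
                self.send_response(200)
                self.send_header("Content-Type", "text/html; charset=utf-8")
                self.send_header("Content-Length", str(len(payload)))
                self.end_headers()
                self.wfile.write(payload)

            def log_message(self, *args):  # keep test output clean
                pass

        self._server = http.server.ThreadingHTTPServer(("127.0.0.1", 0), Handler)
        self._thread = threading.Thread(target=self._server.serve_forever,
                                        daemon=True)

    def __enter__(self) -> "FixtureServer":
        self._thread.start()
        return self

    def __exit__(self, *exc) -> None:
        self._server.shutdown()
        self._server.server_close()

    def url_for(self, path: str) -> str:
        if not path.startswith("/"):
            path = "/" + path
        host, port = self._server.server_address[:2]
        return f"http://{host}:{port}{path}"
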
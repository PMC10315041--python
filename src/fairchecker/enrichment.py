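"""Knowledge-graph enrichment.

Public knowledge graphs (Wikidata, OpenAIRE, OpenCitations) already hold
metadata about many digital resources, cross-referenced by shared
identifiers such as DOIs. Enrichment generates a SPARQL DESCRIBE query per
configured endpoint — selecting nodes linked to the resource's identifier
through the endpoint's bridge property (e.g. Wikidata's P356 DOI property)
— and unions whatever triples come back into the resource graph, before
metric evaluation so retrieved triples count as evidence.

Transports are pluggable: the default offline mode uses fixture transports
returning canned graphs (an exact-query dictionary, or a directory of
Turtle files keyed by query hash); a live SPARQL-protocol transport over
HTTP is available opt-in. Any transport can be wrapped with a TTL cache so
identical queries within the TTL hit the cache instead of the endpoint.
"""

from __future__ import annotations

import hashlib
import logging
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, replace
from pathlib import Path

from rdflib import Graph, Literal, URIRef

from .errors import ContractError
from .harvest import AnnotatedResource
from .metrics import FINDABILITY_PROPERTIES

logger = logging.getLogger(__name__)

QUERY_TEMPLATE_KINDS = ("doi_crossref", "persistent_id", "identifier")


@dataclass(frozen=True)
class EndpointProfile:
    """A public knowledge-graph endpoint and its identifier bridge."""

    name: str
    endpoint_url: str
    bridge_property: str
    query_template_kind: str

    def __post_init__(self) -> None:
        if self.query_template_kind not in QUERY_TEMPLATE_KINDS:
            raise ContractError(
                f"unknown query template kind {self.query_template_kind!r}")


def default_endpoint_profiles() -> list[EndpointProfile]:
    """The shipped endpoint configuration (used live only when opted in)."""
    return [
        EndpointProfile("wikidata", "https://query.wikidata.org/sparql",
                        "http://www.wikidata.org/prop/direct/P356",
                        "doi_crossref"),
        EndpointProfile("openaire", "https://lod.openaire.eu/sparql",
                        "http://lod.openaire.eu/vocab/resPersistentID",
                        "persistent_id"),
        EndpointProfile("opencitations", "https://opencitations.net/sparql",
                        "http://purl.org/spar/datacite/hasIdentifier",
                        "identifier"),
    ]


def normalize_doi(identifier: str) -> str:
    """Strip resolver hosts and the ``doi:`` prefix; case-fold.

    ``https://doi.org/10.1186/X`` and ``DOI:10.1186/x`` both normalise to
    ``10.1186/x`` so the same bridge value matches regardless of how the
    provider wrote the DOI.
    """
    value = identifier.strip()
    lowered = value.lower()
    for prefix in ("https://doi.org/", "http://doi.org/",
                   "https://dx.doi.org/", "http://dx.doi.org/", "doi:"):
        if lowered.startswith(prefix):
            value = value[len(prefix):]
            lowered = value.lower()
    return lowered


def build_describe(resource_identifier: str, profile: EndpointProfile) -> str:
    """Generate the DESCRIBE query retrieving triples about the resource.

    The query describes every node linked to the identifier through the
    profile's bridge property. DOI-crossref endpoints receive the bare,
    case-folded DOI; the others receive the identifier as given.
    """
    if profile.query_template_kind == "doi_crossref":
        value = normalize_doi(resource_identifier)
    else:
        value = resource_identifier.strip()
    escaped = value.replace("\\", "\\\\").replace('"', '\\"')
    return (
        "DESCRIBE ?entity WHERE {\n"
        f'    ?entity <{profile.bridge_property}> "{escaped}" .\n'
        "}"
    )


# ---------------------------------------------------------------------------
# Transports
# ---------------------------------------------------------------------------

def query_hash(endpoint_url: str, query: str) -> str:
    """Stable key for a (endpoint, query) pair, used by directory fixtures."""
    digest = hashlib.sha256(f"{endpoint_url}\n{query}".encode()).hexdigest()
    return digest[:16]


class CannedTransport:
    """Offline transport answering from an in-memory mapping.

    Keys are exact query texts; unknown queries yield the (default empty)
    fallback graph. Counts calls for cache testing.
    """

    def __init__(self, graphs: dict[str, Graph] | None = None,
                 default: Graph | None = None) -> None:
        self._graphs = dict(graphs or {})
        self._default = default if default is not None else Graph()
        self.calls = 0

    def query(self, endpoint_url: str, query: str) -> Graph:
        self.calls += 1
        return self._graphs.get(query, self._default)


class DirectoryTransport:
    """Offline transport reading canned Turtle graphs from a directory.

    The file for a query is ``<query_hash(endpoint, query)>.ttl``; a
    missing file answers the empty graph.
    """

    def __init__(self, directory: str | Path) -> None:
        self._directory = Path(directory)
        self.calls = 0

    def query(self, endpoint_url: str, query: str) -> Graph:
        self.calls += 1
        path = self._directory / f"{query_hash(endpoint_url, query)}.ttl"
        graph = Graph()
        if path.exists():
            graph.parse(path, format="turtle")
        return graph


class HttpSparqlTransport:
    """Live SPARQL-protocol transport (opt-in; requires network)."""

    def __init__(self, timeout: float = 30.0) -> None:
        self.timeout = timeout
        self.calls = 0

    def query(self, endpoint_url: str, query: str) -> Graph:
        self.calls += 1
        data = urllib.parse.urlencode({"query": query}).encode()
        request = urllib.request.Request(
            endpoint_url, data=data,
            headers={"Accept": "text/turtle",
                     "Content-Type": "application/x-www-form-urlencoded",
                     "User-Agent": "fairchecker/0.1"})
        with urllib.request.urlopen(request, timeout=self.timeout) as response:
            body = response.read()
            content_type = (response.headers.get_content_type() or "").lower()
        graph = Graph()
        fmt = {"text/turtle": "turtle", "application/rdf+xml": "xml",
               "application/n-triples": "nt"}.get(content_type, "turtle")
        graph.parse(data=body.decode("utf-8", errors="replace"), format=fmt)
        return graph


class CachedTransport:
    """TTL cache in front of any transport; keys are exact query text."""

    def __init__(self, transport, ttl: float,
                 clock=time.monotonic) -> None:
        if ttl <= 0:
            raise ContractError("ttl must be positive")
        self._transport = transport
        self._ttl = ttl
        self._clock = clock
        self._cache: dict[tuple[str, str], tuple[float, Graph]] = {}

    def query(self, endpoint_url: str, query: str) -> Graph:
        key = (endpoint_url, query)
        now = self._clock()
        hit = self._cache.get(key)
        if hit is not None and now - hit[0] < self._ttl:
            return hit[1]
        graph = self._transport.query(endpoint_url, query)
        self._cache[key] = (now, graph)
        return graph


def cached(transport, ttl: float, clock=time.monotonic) -> CachedTransport:
    """Wrap a transport with a TTL cache."""
    return CachedTransport(transport, ttl, clock=clock)


#: cache lifetimes: resource metadata is short-lived (re-checks should see
#: fresh pages within a minute); registry answers are stable for two weeks.
RESOURCE_CACHE_TTL = 60.0
REGISTRY_CACHE_TTL = 14 * 24 * 3600.0


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def _candidate_identifiers(resource: AnnotatedResource) -> list[str]:
    candidates = [resource.subject_url]
    id_props = {URIRef(p) for p in FINDABILITY_PROPERTIES}
    for s, p, o in resource.graph:
        if p in id_props and isinstance(o, (Literal, URIRef)):
            candidates.append(str(o))
    return candidates


def _looks_like_doi(value: str) -> bool:
    lowered = value.lower()
    return ("doi.org/" in lowered or lowered.startswith("doi:")
            or (lowered.startswith("10.") and "/" in lowered))


def enrich(resource: AnnotatedResource, profiles: list[EndpointProfile],
           transport) -> AnnotatedResource:
    """Union triples retrieved from each endpoint into the resource graph.

    Original triples are never removed (set union, hence idempotent); a
    failing endpoint is logged and skipped so one outage cannot block the
    others.
    """
    merged = Graph()
    for triple in resource.graph:
        merged.add(triple)
    for profile in profiles:
        identifier = resource.subject_url
        if profile.query_template_kind == "doi_crossref":
            dois = [c for c in _candidate_identifiers(resource)
                    if _looks_like_doi(c)]
            if dois:
                identifier = sorted(dois)[0]
        query = build_describe(identifier, profile)
        try:
            retrieved = transport.query(profile.endpoint_url, query)
        except Exception as exc:
            logger.warning("enrichment endpoint %s failed: %s",
                           profile.name, exc)
            continue
        for triple in retrieved:
            merged.add(triple)
    return replace(resource, graph=merged)
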
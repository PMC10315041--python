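"""Harvesting: fetch web documents, extract embedded annotations, and load
pre-assembled RDF dumps for batch assessment.

The central artifact is :class:`AnnotatedResource` — a target URL (or batch
key) together with the RDF graph harvested for it and retrieval provenance.
Everything downstream (metric evaluation, enrichment, profile validation)
operates on this object.
"""

from __future__ import annotations

import logging
import urllib.error
import urllib.request
from collections import deque
from dataclasses import dataclass
from datetime import datetime, timezone
from urllib.parse import urlparse

from rdflib import Graph, URIRef
from rdflib.namespace import RDF

from .errors import ContractError, FormatError, RetrievalError, UnsupportedFeatureError
from .extraction import extract_embedded
from .namespaces import SCHEMA, SCHEMA_HTTPS

logger = logging.getLogger(__name__)

USER_AGENT = "fairchecker/0.1 (FAIR metadata assessment; +https://pypi.org/project/fairchecker)"
MAX_REDIRECTS = 10
DEFAULT_TIMEOUT = 30.0

#: classes whose instances are treated as assessable resources when
#: partitioning a batch dump.
DEFAULT_ROOT_CLASSES: frozenset[URIRef] = frozenset({
    SCHEMA.SoftwareApplication,
    SCHEMA.Dataset,
    SCHEMA.CreativeWork,
    SCHEMA_HTTPS.SoftwareApplication,
    SCHEMA_HTTPS.Dataset,
})

_DUMP_DEPTH_BOUND = 3  # hops followed from a root when partitioning a dump


def is_absolute_uri(value: str) -> bool:
    """True iff *value* is an absolute URI (has a scheme and body)."""
    try:
        parts = urlparse(value)
    except ValueError:
        return False
    if not parts.scheme:
        return False
    return bool(parts.netloc or parts.path)


@dataclass
class AnnotatedResource:
    """A target resource plus its harvested (optionally enriched) graph.

    ``http_status`` is ``None`` when no retrieval was attempted (local file
    or batch dump); ``content_kind`` records whether the graph came from an
    HTML page or a native RDF serialization.
    """

    subject_url: str
    graph: Graph
    http_status: int | None = None
    content_kind: str = "html"  # "html" | "rdf_serialization"
    syntaxes_found: frozenset[str] = frozenset()
    fetched_at: datetime | None = None
    render_js_used: bool = False
    retrieval_error: str | None = None

    def __post_init__(self) -> None:
        if not is_absolute_uri(self.subject_url):
            raise ContractError(
                f"subject_url must be an absolute URI, got {self.subject_url!r}")
        if self.content_kind not in ("html", "rdf_serialization"):
            raise ContractError(f"bad content_kind {self.content_kind!r}")


@dataclass
class FetchResult:
    url: str
    final_url: str
    body: str
    http_status: int
    redirects: int


class _CountingRedirectHandler(urllib.request.HTTPRedirectHandler):
    max_repeats = MAX_REDIRECTS
    max_redirections = MAX_REDIRECTS

    def __init__(self) -> None:
        self.count = 0

    def redirect_request(self, req, fp, code, msg, headers, newurl):
        self.count += 1
        return super().redirect_request(req, fp, code, msg, headers, newurl)


def fetch(url: str, render_js: bool = False,
          timeout: float = DEFAULT_TIMEOUT) -> FetchResult:
    """Retrieve *url* following up to 10 redirects.

    Terminal non-2xx statuses are recorded, not raised — the accessibility
    metric interprets them. Unreachable hosts or timeouts raise
    :class:`RetrievalError`. Client-side JS rendering is not available in
    this installation; requesting it raises ``UnsupportedFeatureError``
    rather than silently degrading.
    """
    scheme = urlparse(url).scheme
    if scheme not in ("http", "https"):
        raise ContractError(f"fetch requires an http(s) URL, got {url!r}")
    if render_js:
        raise UnsupportedFeatureError(
            "client-side rendering requires a browser driver, which this "
            "installation does not provide; re-run without render_js")
    handler = _CountingRedirectHandler()
    opener = urllib.request.build_opener(handler)
    request = urllib.request.Request(url, headers={"User-Agent": USER_AGENT})
    try:
        with opener.open(request, timeout=timeout) as response:
            body = response.read()
            status = response.status
            final_url = response.geturl()
    except urllib.error.HTTPError as err:  # terminal non-2xx
        body = err.read() if err.fp is not None else b""
        status = err.code
        final_url = err.geturl() or url
    except (urllib.error.URLError, TimeoutError, OSError) as err:
        raise RetrievalError(f"cannot retrieve {url}: {err}") from err
    return FetchResult(url=url, final_url=final_url,
                       body=body.decode("utf-8", errors="replace"),
                       http_status=status, redirects=handler.count)


def harvest_url(url: str, render_js: bool = False,
                timeout: float = DEFAULT_TIMEOUT) -> AnnotatedResource:
    """Fetch *url* and extract all embedded annotations into one resource."""
    try:
        result = fetch(url, render_js=render_js, timeout=timeout)
    except RetrievalError as err:
        return AnnotatedResource(subject_url=url, graph=Graph(),
                                 http_status=None,
                                 fetched_at=datetime.now(timezone.utc),
                                 retrieval_error=str(err))
    graph, syntaxes = extract_embedded(result.body, result.final_url)
    return AnnotatedResource(subject_url=url, graph=graph,
                             http_status=result.http_status,
                             syntaxes_found=frozenset(syntaxes),
                             fetched_at=datetime.now(timezone.utc),
                             render_js_used=render_js)


def harvest_file(path: str, base_url: str | None = None) -> AnnotatedResource:
    """Extract embedded annotations from a local HTML file."""
    with open(path, encoding="utf-8") as fh:
        document = fh.read()
    subject = base_url or f"file://{path}"
    graph, syntaxes = extract_embedded(document, subject)
    return AnnotatedResource(subject_url=subject, graph=graph,
                             http_status=None,
                             syntaxes_found=frozenset(syntaxes),
                             fetched_at=datetime.now(timezone.utc))


def make_resource(url_or_key: str, graph: Graph, *,
                  http_status: int | None = None,
                  content_kind: str = "html",
                  syntaxes_found: frozenset[str] | set[str] = frozenset(),
                  render_js_used: bool = False) -> AnnotatedResource:
    """Bundle harvest output into an :class:`AnnotatedResource`, enforcing
    its invariants (absolute subject URL, known content kind)."""
    return AnnotatedResource(subject_url=url_or_key, graph=graph,
                             http_status=http_status,
                             content_kind=content_kind,
                             syntaxes_found=frozenset(syntaxes_found),
                             fetched_at=datetime.now(timezone.utc),
                             render_js_used=render_js_used)


_SERIALIZATION_FORMATS = {
    "turtle": "turtle",
    "ntriples": "nt",
    "json-ld": "json-ld",
    "rdfxml": "xml",
}


def load_dump(path: str, serialization: str = "turtle",
              root_classes: frozenset[URIRef] | set[URIRef] = DEFAULT_ROOT_CLASSES,
              depth: int = _DUMP_DEPTH_BOUND) -> dict[str, Graph]:
    """Partition an RDF dump into per-resource sub-graphs.

    Roots are subjects carrying an ``rdf:type`` among *root_classes*. Each
    root's sub-graph collects every triple reachable from it by following
    objects up to *depth* hops; traversal never expands into another root's
    node, so resources sharing the dump do not bleed into one another.
    """
    if serialization not in _SERIALIZATION_FORMATS:
        raise ContractError(f"unknown serialization {serialization!r}")
    graph = Graph()
    try:
        graph.parse(path, format=_SERIALIZATION_FORMATS[serialization])
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as {serialization}: {exc}") from exc

    roots = sorted({s for cls in root_classes for s in graph.subjects(RDF.type, cls)
                    if isinstance(s, URIRef)})
    root_set = set(roots)
    by_subject: dict = {}
    for triple in graph:
        by_subject.setdefault(triple[0], []).append(triple)

    partition: dict[str, Graph] = {}
    for root in roots:
        sub = Graph()
        seen = {root}
        queue = deque([(root, 0)])
        while queue:
            node, d = queue.popleft()
            for s, p, o in by_subject.get(node, ()):
                sub.add((s, p, o))
                if d < depth and o not in seen and o not in root_set \
                        and o in by_subject:
                    seen.add(o)
                    queue.append((o, d + 1))
        partition[str(root)] = sub
    return partition
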
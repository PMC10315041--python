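"""Vocabulary-registry support: which classes/properties does a graph use,
and are they registered in a term catalog?

Two catalog kinds mirror the registry landscape: *general* Semantic Web
registries (LOV-like coverage: Schema.org, Dublin Core, PROV, PAV, DCAT...)
and *domain* life-science registries (OLS/BioPortal-like coverage: EDAM,
OBO). The default backends are local fixture catalogs shipped with the
package so assessments are hermetic; live registry clients can be plugged
in through the same :class:`TermCatalog` interface.

Matching is namespace-level by default (a term is known when its namespace
is covered); term-level matching applies when a catalog enumerates
``known_terms``. The rdf/rdfs/owl/xsd namespaces are infrastructure: always
known, excluded from coverage denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from rdflib import BNode, Graph, URIRef
from rdflib.namespace import RDF

from .namespaces import INFRASTRUCTURE_NAMESPACES


@dataclass(frozen=True)
class TermCatalog:
    """A vocabulary catalog: a named set of known namespaces and/or terms."""

    name: str
    kind: str  # "general" | "domain"
    known_namespaces: frozenset[str] = frozenset()
    known_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("general", "domain"):
            raise ValueError(f"catalog kind must be general|domain, got {self.kind!r}")
        for term in self.known_terms:
            if not any(term.startswith(ns) for ns in self.known_namespaces):
                raise ValueError(
                    f"known term {term} outside every known namespace of {self.name}")

    def knows(self, term: str) -> bool:
        if term in self.known_terms:
            return True
        return any(term.startswith(ns) for ns in self.known_namespaces)


def _load_catalog_file(filename: str, name: str, kind: str) -> TermCatalog:
    text = (resources.files("fairchecker") / "data" / "catalogs" / filename
            ).read_text(encoding="utf-8")
    namespaces = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            namespaces.add(line)
    return TermCatalog(name=name, kind=kind, known_namespaces=frozenset(namespaces))


def default_catalogs() -> list[TermCatalog]:
    """The shipped offline catalogs: one general, one life-science domain."""
    return [
        _load_catalog_file("general.txt", "local-general", "general"),
        _load_catalog_file("domain.txt", "local-life-science", "domain"),
    ]


def is_infrastructure(term: str) -> bool:
    return any(term.startswith(ns) for ns in INFRASTRUCTURE_NAMESPACES)


def used_terms(graph: Graph) -> tuple[set[str], set[str]]:
    """Classes and properties a graph uses.

    Properties are all predicates; classes are IRI objects of ``rdf:type``.
    Blank nodes and literals are excluded.
    """
    properties = {str(p) for _, p, _ in graph}
    classes = {str(o) for o in graph.objects(None, RDF.type)
               if isinstance(o, URIRef) and not isinstance(o, BNode)}
    return classes, properties


def lookup(term: str, catalogs: list[TermCatalog]) -> dict[str, bool]:
    """Per-catalog known/unknown verdicts for one term."""
    return {catalog.name: catalog.knows(term) for catalog in catalogs}


def known_to_any(term: str, catalogs: list[TermCatalog],
                 kind: str | None = None) -> bool:
    if is_infrastructure(term):
        return True
    return any(c.knows(term) for c in catalogs if kind is None or c.kind == kind)


@dataclass
class Coverage:
    fraction: float
    n_known: int
    n_terms: int
    empty: bool = field(default=False)


def coverage(graph: Graph, catalogs: list[TermCatalog]) -> dict[str, Coverage]:
    """Fraction of (non-infrastructure) used terms known, per catalog kind."""
    classes, properties = used_terms(graph)
    terms = sorted(t for t in classes | properties if not is_infrastructure(t))
    out: dict[str, Coverage] = {}
    for kind in ("general", "domain"):
        kind_catalogs = [c for c in catalogs if c.kind == kind]
        if not terms:
            out[kind] = Coverage(0.0, 0, 0, empty=True)
            continue
        n_known = sum(1 for t in terms if any(c.knows(t) for c in kind_catalogs))
        out[kind] = Coverage(n_known / len(terms), n_known, len(terms))
    return out
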
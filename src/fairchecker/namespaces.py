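"""Shared vocabulary namespaces and the prefix map used across the package.

The metric property sets (findability identifiers, accessibility, license,
provenance) reference terms from these vocabularies; keeping a single prefix
map guarantees that generated SPARQL, generated SHACL and humanized report
messages all render the same prefixed names.
"""

from __future__ import annotations

from rdflib import Namespace
from rdflib.namespace import DCTERMS as DCT  # noqa: F401  (re-export)
from rdflib.namespace import OWL, PROV, RDF, RDFS, XSD  # noqa: F401

SCHEMA = Namespace("http://schema.org/")
SCHEMA_HTTPS = Namespace("https://schema.org/")
DCAT = Namespace("http://www.w3.org/ns/dcat#")
PAV = Namespace("http://purl.org/pav/")
ODRL = Namespace("http://www.w3.org/ns/odrl/2/")
DOAP = Namespace("http://usefulinc.com/ns/doap#")
DBO = Namespace("http://dbpedia.org/ontology/")
CC = Namespace("http://creativecommons.org/ns#")
XHV = Namespace("http://www.w3.org/1999/xhtml/vocab#")
STO = Namespace("https://w3id.org/i40/sto#")
NIE = Namespace("http://www.semanticdesktop.org/ontologies/2007/01/19/nie#")
SH = Namespace("http://www.w3.org/ns/shacl#")
EDAM = Namespace("http://edamontology.org/")
BSP = Namespace("https://bioschemas.org/profiles/")

#: prefix -> namespace, used for query/shape generation and message rendering.
PREFIXES: dict[str, Namespace] = {
    "rdf": RDF,
    "rdfs": RDFS,
    "owl": OWL,
    "xsd": XSD,
    "schema": SCHEMA,
    "dct": DCT,
    "dcat": DCAT,
    "prov": PROV,
    "pav": PAV,
    "odrl": ODRL,
    "doap": DOAP,
    "dbo": DBO,
    "cc": CC,
    "xhv": XHV,
    "sto": STO,
    "nie": NIE,
    "sh": SH,
    "edam": EDAM,
}

#: namespaces that belong to the RDF machinery itself; they are treated as
#: known everywhere and excluded from vocabulary-coverage denominators.
INFRASTRUCTURE_NAMESPACES: tuple[str, ...] = (
    str(RDF),
    str(RDFS),
    str(OWL),
    str(XSD),
)


def prefixed(iri: str) -> str:
    """Render an IRI with a well-known prefix when possible, e.g.
    ``http://schema.org/name`` -> ``schema:name``; otherwise return the IRI.
    """
    best_prefix, best_ns = None, ""
    for prefix, ns in PREFIXES.items():
        ns_str = str(ns)
        if iri.startswith(ns_str) and len(ns_str) > len(best_ns):
            best_prefix, best_ns = prefix, ns_str
    if best_prefix is None:
        return iri
    local = iri[len(best_ns):]
    if not local or any(c in local for c in "/#:"):
        return iri
    return f"{best_prefix}:{local}"
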
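"""Extraction of embedded structured annotations from HTML documents.

Three embedding syntaxes are supported, mirroring what web search engines
consume: JSON-LD ``<script>`` blocks, RDFa Lite attributes, and HTML
microdata. All triples are merged into one rdflib :class:`~rdflib.Graph`
with set semantics (a statement asserted by two syntaxes appears once);
blank nodes minted for distinct syntax blocks are never merged.

JSON-LD is delegated to rdflib's parser. RDFa and microdata are covered by
tolerant in-package extractors over ``lxml`` implementing the Lite subset
found in practice on annotated life-science pages: ``vocab``/``prefix``/
``about``/``typeof``/``property``/``resource``/``href``/``src``/``content``
for RDFa, and ``itemscope``/``itemtype``/``itemid``/``itemprop`` for
microdata. Malformed fragments are skipped with a logged warning, never
fatal.
"""

from __future__ import annotations

import logging
from urllib.parse import urljoin

from lxml import html as lxml_html
from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import RDF

from .namespaces import PREFIXES

logger = logging.getLogger(__name__)

JSONLD_MIME = "application/ld+json"

#: RDFa initial-context prefixes available without declaration.
_RDFA_DEFAULT_PREFIXES = {p: str(ns) for p, ns in PREFIXES.items()}


def _document_base(tree, fallback: str) -> str:
    for el in tree.iter("base"):
        href = el.get("href")
        if href:
            return urljoin(fallback, href)
    return fallback


def parse_html(document: str):
    """Tolerantly parse an HTML document into an lxml tree."""
    parser = lxml_html.HTMLParser(recover=True)
    return lxml_html.fromstring(document or "<html></html>", parser=parser)


# ---------------------------------------------------------------------------
# JSON-LD
# ---------------------------------------------------------------------------

def extract_jsonld(tree, base_url: str) -> Graph:
    """Parse every ``<script type="application/ld+json">`` block.

    Each block is parsed independently so one malformed block cannot abort
    the others; rdflib mints per-parse blank nodes, so blank nodes from
    distinct blocks stay distinct.
    """
    out = Graph()
    for script in tree.iter("script"):
        mime = (script.get("type") or "").split(";")[0].strip().lower()
        if mime != JSONLD_MIME:
            continue
        body = script.text or ""
        if not body.strip():
            continue
        try:
            block = Graph()
            block.parse(data=body, format="json-ld", publicID=base_url)
        except Exception as exc:  # malformed block: skip, keep going
            logger.warning("skipping malformed JSON-LD block: %s", exc)
            continue
        for triple in block:
            out.add(triple)
    return out


# ---------------------------------------------------------------------------
# RDFa Lite
# ---------------------------------------------------------------------------

def _rdfa_prefixes(attr_value: str, inherited: dict[str, str]) -> dict[str, str]:
    mapping = dict(inherited)
    tokens = attr_value.split()
    for name, iri in zip(tokens[::2], tokens[1::2]):
        if name.endswith(":"):
            mapping[name[:-1]] = iri
    return mapping


def _rdfa_term_iri(term: str, vocab: str | None, prefixes: dict[str, str],
                   base_url: str) -> URIRef | None:
    term = term.strip()
    if not term:
        return None
    if term.startswith(("http://", "https://")):
        return URIRef(term)
    if ":" in term:
        prefix, local = term.split(":", 1)
        ns = prefixes.get(prefix)
        if ns:
            return URIRef(ns + local)
        return None
    if vocab:
        return URIRef(vocab + term)
    return None


def extract_rdfa(tree, base_url: str) -> Graph:
    """Extract RDFa Lite annotations by a single recursive tree walk."""
    out = Graph()

    def walk(el, subject, vocab, prefixes):
        if not isinstance(el.tag, str):  # comments / PIs
            for child in el:
                walk(child, subject, vocab, prefixes)
            return
        vocab = el.get("vocab") or vocab
        if el.get("prefix"):
            prefixes = _rdfa_prefixes(el.get("prefix"), prefixes)

        about = el.get("about")
        resource = el.get("resource")
        typeof = el.get("typeof")
        prop = el.get("property")
        href = el.get("href") or el.get("src")

        new_subject = subject
        if about is not None:
            new_subject = URIRef(urljoin(base_url, about))
        elif typeof is not None and prop is None:
            # typed element without property starts a fresh node
            if resource is not None:
                new_subject = URIRef(urljoin(base_url, resource))
            elif href is not None:
                new_subject = URIRef(urljoin(base_url, href))
            else:
                new_subject = BNode()

        if prop is not None:
            # property element: object is a resource, a nested typed node,
            # an explicit content literal, or the text content
            if typeof is not None and about is None:
                obj = (URIRef(urljoin(base_url, resource)) if resource is not None
                       else BNode())
            elif resource is not None:
                obj = URIRef(urljoin(base_url, resource))
            elif href is not None:
                obj = URIRef(urljoin(base_url, href))
            elif el.get("content") is not None:
                obj = Literal(el.get("content"))
            else:
                obj = Literal("".join(el.itertext()).strip())
            if subject is not None:
                for term in prop.split():
                    p_iri = _rdfa_term_iri(term, vocab, prefixes, base_url)
                    if p_iri is not None:
                        out.add((subject, p_iri, obj))
            if typeof is not None and about is None:
                new_subject = obj if isinstance(obj, (URIRef, BNode)) else subject

        if typeof is not None and new_subject is not None:
            for term in typeof.split():
                t_iri = _rdfa_term_iri(term, vocab, prefixes, base_url)
                if t_iri is not None:
                    out.add((new_subject, RDF.type, t_iri))

        for child in el:
            walk(child, new_subject, vocab, prefixes)

    root_subject = URIRef(base_url) if base_url else None
    walk(tree, root_subject, None, dict(_RDFA_DEFAULT_PREFIXES))
    return out


# ---------------------------------------------------------------------------
# HTML microdata
# ---------------------------------------------------------------------------

def _microdata_prop_iri(name: str, itemtype: str | None) -> URIRef | None:
    name = name.strip()
    if not name:
        return None
    if name.startswith(("http://", "https://")):
        return URIRef(name)
    if itemtype:
        cut = max(itemtype.rfind("/"), itemtype.rfind("#"))
        if cut >= 0:
            return URIRef(itemtype[: cut + 1] + name)
    return None


def extract_microdata(tree, base_url: str) -> Graph:
    """Extract HTML microdata items (``itemref`` is not supported).

    Items without ``itemid`` become blank nodes, so callers should compare
    triple counts rather than node identity for such items.
    """
    out = Graph()

    def item_subject(el):
        itemid = el.get("itemid")
        if itemid:
            return URIRef(urljoin(base_url, itemid))
        return BNode()

    def process_item(el, subject):
        itemtype = None
        for t in (el.get("itemtype") or "").split():
            itemtype = itemtype or t
            out.add((subject, RDF.type, URIRef(t)))

        def scan(node):
            for child in node:
                if not isinstance(child.tag, str):
                    scan(child)
                    continue
                prop = child.get("itemprop")
                nested = child.get("itemscope") is not None
                if prop is not None:
                    if nested:
                        value = item_subject(child)
                        process_item(child, value)
                    elif child.tag in ("a", "link", "area") and child.get("href"):
                        value = URIRef(urljoin(base_url, child.get("href")))
                    elif child.tag in ("img", "audio", "video", "embed",
                                       "iframe", "source") and child.get("src"):
                        value = URIRef(urljoin(base_url, child.get("src")))
                    elif child.get("content") is not None:
                        value = Literal(child.get("content"))
                    elif child.tag == "time" and child.get("datetime"):
                        value = Literal(child.get("datetime"))
                    else:
                        value = Literal("".join(child.itertext()).strip())
                    for name in prop.split():
                        p_iri = _microdata_prop_iri(name, itemtype)
                        if p_iri is not None:
                            out.add((subject, p_iri, value))
                    if not nested:
                        scan(child)
                elif nested:
                    continue  # independent item; handled by the top-level loop
                else:
                    scan(child)

        scan(el)

    for el in tree.iter():
        if isinstance(el.tag, str) and el.get("itemscope") is not None \
                and el.get("itemprop") is None:
            process_item(el, item_subject(el))
    return out


# ---------------------------------------------------------------------------
# Combined
# ---------------------------------------------------------------------------

def extract_embedded(document: str, base_url: str) -> tuple[Graph, set[str]]:
    """Extract all embedded annotations from an HTML document.

    Returns the deduplicated union graph over the three syntaxes and the
    set of syntaxes that actually contributed at least one triple
    (a subset of ``{"json-ld", "rdfa", "microdata"}``). Relative IRIs are
    resolved against the document's declared ``<base>`` if present, else
    ``base_url``.
    """
    tree = parse_html(document)
    base = _document_base(tree, base_url)
    merged = Graph()
    syntaxes: set[str] = set()
    for name, extractor in (("json-ld", extract_jsonld),
                            ("rdfa", extract_rdfa),
                            ("microdata", extract_microdata)):
        try:
            part = extractor(tree, base)
        except Exception as exc:
            logger.warning("%s extraction failed: %s", name, exc)
            continue
        if len(part):
            syntaxes.add(name)
        for triple in part:
            merged.add(triple)
    return merged, syntaxes
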
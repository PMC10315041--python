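"""Actionable guidance attached to failing metrics.

Each failing metric maps to a short explanation of how to improve the
metadata, with pointers into community training material (FAIR Cookbook
recipes) and, where the fix is "use one of these properties", the concrete
property list.
"""

from __future__ import annotations

from .errors import ContractError

#: FAIR Cookbook recipe identifiers referenced by the guidance texts.
COOKBOOK_LINKS = {
    "recipe-1-identifiers": "https://faircookbook.elixir-europe.org/content/recipes/findability/identifiers.html",
    "recipe-8-seo": "https://faircookbook.elixir-europe.org/content/recipes/findability/seo.html",
    "recipe-3-terminologies": "https://faircookbook.elixir-europe.org/content/recipes/interoperability/introduction-terminologies-ontologies.html",
    "recipe-4-ontology-selection": "https://faircookbook.elixir-europe.org/content/recipes/interoperability/selecting-ontologies.html",
}

_RECOMMENDATIONS: dict[str, tuple[str, tuple[str, ...]]] = {
    "F1A": ("Identify the resource with a syntactically valid absolute URI "
            "(a URL is sufficient).", ()),
    "F1B": ("Assign a unique and persistent identifier (DOI, Identifiers.org, "
            "purl or w3id) and expose it with schema:identifier or "
            "dct:identifier; see the FAIR Cookbook recipe 1 on unique and "
            "persistent identifiers.", ("recipe-1-identifiers",)),
    "F2A": ("Embed structured metadata (for example a JSON-LD block using "
            "Schema.org) in the resource page; the FAIR Cookbook recipe 8 on "
            "Search Engine Optimisation shows worked examples.",
            ("recipe-8-seo",)),
    "F2B": ("Describe the resource with terms from shared, registered "
            "vocabularies; FAIR Cookbook recipes 3 and 4 introduce "
            "terminologies and how to select appropriate ontologies.",
            ("recipe-3-terminologies", "recipe-4-ontology-selection")),
    "A1.1": ("Serve the resource over an open, free protocol (HTTP/HTTPS) at "
             "a resolvable URL.", ()),
    "A1.2": ("Declare how the resource can be accessed, e.g. with "
             "dct:accessRights, dcat:accessURL, dcat:downloadURL or "
             "odrl:hasPolicy.", ()),
    "I1": ("Expose metadata in a formal knowledge-representation language: "
           "embed RDF via JSON-LD, RDFa or microdata, or publish a native "
           "RDF serialization.", ()),
    "I2": ("Use only vocabularies that are themselves registered and "
           "resolvable (e.g. listed in LOV, OLS or BioPortal); FAIR Cookbook "
           "recipes 3 and 4 help with selection.",
           ("recipe-3-terminologies", "recipe-4-ontology-selection")),
    "I3": ("Link the resource to other resources with qualified references "
           "(IRIs under external authorities), e.g. schema:citation or "
           "schema:sameAs.", ()),
    "R1.1": ("Attach a machine-readable license using one of: "
             "schema:license, dct:license, doap:license, dbpedia-owl:license "
             "or cc:license.", ()),
    "R1.2": ("Describe provenance with PROV, PAV or DC-Terms, e.g. "
             "prov:wasGeneratedBy, pav:authoredBy, dct:creator, "
             "dct:hasVersion.", ()),
    "R1.3": ("Annotate the resource with domain community standards (e.g. "
             "the EDAM ontology for bioinformatics resources) or declare a "
             "community profile with dct:conformsTo and satisfy its minimum "
             "properties.", ()),
}


def recommendation_for(metric_id: str, status: str) -> tuple[str, tuple[str, ...]]:
    """Guidance text and resource-link keys for a metric outcome.

    Passing metrics yield an empty recommendation; unknown metric ids are a
    caller error.
    """
    if metric_id not in _RECOMMENDATIONS:
        raise ContractError(f"unknown metric id {metric_id!r}")
    if status == "pass":
        return "", ()
    return _RECOMMENDATIONS[metric_id]
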
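# General Semantic Web vocabulary namespaces (LOV-like offline coverage).
# One namespace IRI prefix per line; '#' starts a comment.
http://schema.org/
https://schema.org/
http://purl.org/dc/terms/
http://purl.org/dc/elements/1.1/
http://www.w3.org/ns/dcat#
http://www.w3.org/ns/prov#
http://purl.org/pav/
http://www.w3.org/ns/odrl/2/
http://usefulinc.com/ns/doap#
http://dbpedia.org/ontology/
http://creativecommons.org/ns#
http://www.w3.org/1999/xhtml/vocab#
https://w3id.org/i40/sto#
http://www.semanticdesktop.org/ontologies/2007/01/19/nie#
http://xmlns.com/foaf/0.1/
http://www.w3.org/2004/02/skos/core#
http://rdfs.org/ns/void#
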
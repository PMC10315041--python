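# Life-science vocabulary namespaces (OLS/BioPortal-like offline coverage).
http://edamontology.org/
http://purl.obolibrary.org/obo/
https://bioschemas.org/
http://semanticscience.org/resource/
http://purl.uniprot.org/core/
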
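# fairchecker

Automated FAIR-maturity assessment for web-published life-science digital
resources — datasets, bioinformatics tools, training materials — from the
machine-readable metadata they expose.

Data producers, software developers and registry maintainers are asked to
make their resources Findable, Accessible, Interoperable and Reusable, but
testing a web page against the FAIR principles by hand requires Semantic
Web expertise most of them do not have. `fairchecker` automates the loop:

1. **Harvest** — fetch a page and extract every embedded annotation
   (JSON-LD, RDFa, HTML microdata) into one RDF graph; or load a native
   RDF dump of a whole registry for batch assessment.
2. **Evaluate** — test twelve FAIR maturity indicators (F1A, F1B, F2A,
   F2B, A1.1, A1.2, I1, I2, I3, R1.1, R1.2, R1.3). Property-based
   indicators are operationalized as generated SPARQL ASK queries: for a
   metric with target properties `p₁ … pₖ` the engine emits

   ```sparql
   ASK {
       VALUES ?p { <p₁> ... <pₖ> }
       ?s ?p ?o .
   }
   ```

   which answers true iff at least one target property occurs as a
   predicate. The curated target sets cover identifier/title properties
   (F1B), access declarations (A1.2), license properties
   (`schema:license`, `dct:license`, `doap:license`, `dbo:license`,
   `cc:license`, ...) for R1.1 and PROV/PAV/DC-Terms/Schema.org provenance
   properties for R1.2. The remaining indicators test the identifier
   syntax and persistence scheme (DOI, Identifiers.org, purl, w3id), the
   retrieval protocol, the use of registered vocabularies (general and
   life-science registries), and qualified external references.
3. **Enrich** (optional) — generate SPARQL DESCRIBE queries against public
   knowledge graphs (Wikidata via its DOI cross-reference property P356,
   OpenAIRE, OpenCitations) and union the retrieved triples into the
   resource graph before evaluation.
4. **Inspect** — validate an entity against a community metadata profile
   (Bioschemas-style). Each profile's property buckets are compiled from a
   single SHACL shape template: *minimum* properties become
   `sh:Violation`-severity property shapes, *recommended* properties
   `sh:Warning`-severity shapes, each with a `sh:minCount 1` presence
   constraint. Missing minimum properties are reported as requirements
   ("must be provided"), missing recommended properties as improvements
   ("should be provided").
5. **Report** — per-resource reports with actionable recommendations
   (including FAIR Cookbook pointers), and batch aggregates: the exact
   partition of resources by identical pass/fail vector (UpSet-ready) and
   entry-wise recommended-property completeness.

Everything runs offline by default against shipped vocabulary catalogs and
frozen profile documents; live registries and SPARQL endpoints are opt-in.

## Worked example

Serve the two bundled fixture pages — a plain landing page without
embedded metadata, and the same software page annotated with the
ComputationalTool profile plus EDAM ontology terms — and check both:

```python
from fairchecker import evaluate_all, harvest_url
from fairchecker.fixtures import (FixtureServer, make_bare_page,
                                  make_computational_tool_page)

pages = {"/bare.html": make_bare_page(),
         "/tool.html": make_computational_tool_page()}
with FixtureServer(pages) as server:
    for path in ("/bare.html", "/tool.html"):
        results = evaluate_all(harvest_url(server.url_for(path)))
        passed = [r.metric_id for r in results if r.status == "pass"]
        print(path, len(passed), passed)
```

prints

```
/bare.html 2 ['F1A', 'A1.1']
/tool.html 10 ['F1A', 'F1B', 'F2A', 'F2B', 'A1.1', 'A1.2', 'I1', 'I2', 'I3', 'R1.3']
```

The bare page validates only the two indicators that come for free with a
working URL (globally unique identifier, open retrieval protocol). After
annotation, ten of twelve validate; the two failures, R1.1 (no license
statement) and R1.2 (no provenance), come back with recommendations naming
the exact properties that would fix them.

The same assessments are available from a shell:

```bash
fairchecker check  https://example.org/tool.html --format json
fairchecker inspect page.html --profile ComputationalTool --emit-shapes shapes/
fairchecker batch  registry-dump.ttl --out summary.json --membership-matrix m.csv
```

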
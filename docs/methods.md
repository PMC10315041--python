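# Methods

## Assessment model

A *resource* is a URL (or batch key) plus the RDF graph harvested for it.
Assessment is purely metadata-driven: the engine never judges the data
behind the page, only what the page (or dump) says about it in
machine-readable form. Twelve FAIR maturity indicators are evaluated,
each as a boolean test with evidence:

| id | test | kind |
|----|------|------|
| F1A | the identifier is a syntactically valid absolute URI | structure |
| F1B | an identifier/title property from the findability set is present, **or** the URL itself uses a persistent scheme (DOI, Identifiers.org, purl.*, w3id.org) | property / scheme |
| F2A | the harvested graph is non-empty | structure |
| F2B | at least one used term belongs to a registered vocabulary | registry |
| A1.1 | the scheme is http/https/ftp and retrieval terminated below 400 | protocol |
| A1.2 | an access-declaration property is present (`odrl:hasPolicy`, `dct:rights`, `dct:accessRights`, `dcat:accessURL`, `dcat:downloadURL`, `dcat:endpointDescription`, `dcat:endpointURL`, `schema:downloadUrl`) | property |
| I1 | at least one triple came from a standard RDF syntax (embedded or native) | structure |
| I2 | **every** used non-infrastructure namespace is known to at least one registry; fails vacuously on an empty graph | registry |
| I3 | some non-`rdf:type` triple points to an IRI under a different authority than the resource's own | reference |
| R1.1 | a license property is present (8-property set across Schema.org, DC-Terms, DOAP, DBpedia, CC, XHTML-vocab, STO, NIE) | property |
| R1.2 | a provenance property is present (31-property set across PROV, PAV, DC-Terms, Schema.org) | property |
| R1.3 | a used term belongs to a *domain* (life-science) registry, or the entity conforms to a community profile with zero violations | registry |

Long-term-preservation (A2) and F3 are deliberately not assessed: neither
has a workable metadata-level test. Results are pass/fail vectors with
priorities reported but never weighted into a numeric score.

Property-presence tests are executed as generated SPARQL ASK queries with
a VALUES clause enumerating the target properties; evidence is the list of
matching triples. All target sets are module constants, and a
factory-style registry lets alternative implementations of any indicator
be registered and selected by name.

### Design choices worth knowing

- **F1B disjunction.** Either a declared identifier property or a
  persistent URL scheme satisfies F1B; the evidence records which branch
  fired. Requiring both would punish pages that do one thing well.
- **A1.1 on dumps.** Batch resources are never fetched, so the protocol
  test degrades to the identifier-scheme check for graphs loaded from a
  native RDF serialization. When a fetch *was* attempted, a terminal
  status ≥ 400 or a retrieval failure fails the metric.
- **I2 is universal, hence non-monotone.** Every used namespace must be
  registered; a namespace unknown to all backends is a failure, not an
  error. Consequently adding a triple in an unregistered vocabulary can
  flip I2 from pass to fail — the only indicator with this behaviour. The
  monotonicity guarantees below are therefore stated for additions drawn
  from registered vocabularies (which is what enrichment from curated
  knowledge graphs produces); the other eleven indicators are monotone
  under arbitrary additions, and the test suite pins both facts.
- **Infrastructure namespaces** (rdf, rdfs, owl, xsd) are always treated
  as known and excluded from coverage denominators, so `rdf:type` alone
  never makes a graph "use shared vocabularies".
- **I3 exclusions.** `rdf:type` objects and same-authority IRIs do not
  count as qualified references: a reference qualifies only when it leaves
  the resource's own authority.

## Harvesting

JSON-LD blocks are parsed per block (one malformed block is skipped with
a warning, never fatal), so blank nodes from distinct blocks stay
distinct; RDFa Lite and microdata are covered by tolerant extractors over
lxml implementing the attribute subset found on annotated life-science
pages (`vocab`/`prefix`/`about`/`typeof`/`property`/`resource`/`href`/
`content`; `itemscope`/`itemtype`/`itemid`/`itemprop`; `itemref` is not
supported). Triples from all syntaxes merge with set semantics. Relative
IRIs resolve against the document's declared `<base>`, else the final
post-redirect URL. HTTP fetching follows up to 10 redirects, uses a
30-second default timeout and a descriptive user agent, records terminal
non-2xx statuses instead of raising, and leaves client-side JS rendering
as an explicit, unavailable-by-default flag so results stay reproducible.

Batch dumps are partitioned by root subjects — subjects typed with a
configurable set of root classes — collecting triples reachable by
following objects up to 3 hops, never expanding into another root's node,
so resources in a shared dump cannot bleed into each other. The 3-hop
bound comfortably covers the nesting depth of typical Schema.org
annotations (entity → sub-entity → value).

## Enrichment

For each configured endpoint, a DESCRIBE query selects nodes linked to
the resource's identifier through that endpoint's bridge property
(Wikidata P356 for DOIs, OpenAIRE's persistent-id property, DataCite's
`hasIdentifier`). DOIs are normalized (resolver host and `doi:` prefix
stripped, case-folded) before injection. Retrieved triples union into the
resource graph *before* metric evaluation, so they count as evidence;
union semantics make enrichment idempotent and strictly additive. Each
endpoint failure is logged and skipped. Transports are pluggable; offline
fixture transports (exact-query dictionary, or directory of Turtle files
keyed by a 16-hex-digit query hash) make all tests hermetic. A TTL cache
can wrap any transport: 60 s for resource metadata, 14 days for registry
answers — the first keeps interactive re-checks fresh, the second spares
stable terminology services.

## Vocabulary registries

Offline catalogs ship with the package as plain-text namespace lists: a
*general* catalog (Schema.org, DC-Terms, DCAT, PROV, PAV, ODRL, DOAP,
DBpedia, CC, FOAF, SKOS, VoID…) standing in for LOV-style coverage, and a
*domain* catalog (EDAM, OBO, Bioschemas, SIO, UniProt core) standing in
for OLS/BioPortal-style coverage. Matching is namespace-level by default;
term-level matching applies when a catalog enumerates known terms. Live
registry clients plug into the same catalog interface but are opt-in and
deliberately unexercised by the test suite.

## Profiles and SHACL

Profile specifications are JSON-LD documents declaring a name, a target
class and a property list bucketed by marginality (minimum / recommended /
optional). Two frozen profiles ship in-repo — ComputationalTool (minimum:
name, description, url; recommended: applicationCategory, citation,
downloadUrl, featureList, operatingSystem, softwareVersion) and Gene
(minimum: identifier, name; recommended: description, url) — so tests do
not track any live specification repository; their `@id` fields record
the upstream profile URLs for provenance.

A single text template produces each profile's SHACL shape: one node
shape targeting the profile class, one property shape per minimum
property at `sh:Violation` severity and per recommended property at
`sh:Warning` severity, each constraining presence only (`sh:minCount 1`).
Property shapes are emitted in sorted order so shape files are bit-stable
and diff cleanly. Optional-marginality properties are parsed but generate
no constraint: an Info-severity shape would change report semantics
without adding actionable guidance. Cardinality above presence is out of
scope.

Validation interprets exactly this generated subset (targetClass / path /
minCount 1 / severity) with an in-package checker: a focus entity
violates a Violation shape when it has zero occurrences of the path
property, and accrues a warning likewise. This keeps validation
deterministic and dependency-free; shapes are still standard SHACL
Turtle, exportable (`--emit-shapes`) and consumable by any external SHACL
engine.

Profile selection honours a provider's `dct:conformsTo` declaration
first, then matches `rdf:type` against profile target classes (modulo an
http/https Schema.org alias map); ties break toward the profile with more
minimum properties already present, then the lexicographically smaller
name — one best profile per entity.

## Reporting and batch statistics

Each failing metric carries a recommendation: short guidance plus FAIR
Cookbook pointers (persistent identifiers, structured-markup/SEO,
terminology selection) and, for the license metric, the concrete property
list to use. Batch aggregation partitions resources by identical
pass/fail vector — exactly the membership input an UpSet plot consumes —
and completeness is the entry-wise mean of
`(|recommended| − warnings) / |recommended|` over profile-matched
entities (mean over entries, not over properties; a profile with no
recommended properties is trivially complete). Exports (JSON, RFC-4180
CSV, Markdown, 0/1 membership matrix) use stable field ordering and
contain no timestamps, so offline runs are byte-identical.

## Synthetic fixtures: what they emulate and what they do not

The fixture generators produce the study conditions end to end: a bare
landing page (zero extractable triples), a ComputationalTool-annotated
page (all minimum+recommended properties, `schema:identifier`, EDAM
topic/operation terms attached as `rdf:type`s of category/feature nodes,
a download link; no license, no provenance unless requested), arbitrary
single-syntax pages from triple recipes (round-trip exact by
construction), profile documents that round-trip through the parser, and
batch dumps with a ground-truth ledger.

Batch prescriptions toggle the eight indicators a dump resource can
actually vary (F1B, A1.1, A1.2, I2, I3, R1.1, R1.2, R1.3); the other four
are structurally true for dump resources — subjects are absolute IRIs
carrying non-empty native-RDF graphs built from registered vocabularies —
and the generator rejects prescriptions it cannot realize (e.g. all six
recommended properties present while failing A1.2, since the download
link is itself an access declaration). Default sampling probabilities are
shaped like a large software-registry dump: licenses are the common gap
and provenance is never exposed. Dumps are emitted as sorted N-Triples,
byte-identical per seed.

Passing against these fixtures shows the pipeline is correct on
well-formed annotations and dumps; it does not show robustness to the
full diversity of real-world markup (exotic RDFa constructs, `itemref`
microdata, content negotiation, JS-rendered pages) nor anything about the
behaviour of live registries and endpoints, which are mocked throughout.

## Problem sizes and numerical notes

The randomized suites use 1000 ASK-oracle cases on graphs of ≤ 50
triples, 50 random profiles for the shape-count law, 500 random
augmentations for the monotonicity suites, and a 500-resource synthetic
batch — sizes at which every law is exercised densely while the whole
acceptance run stays under a minute on one CPU. All randomness is driven
by explicit seeds; completeness means are reproduced exactly (identical
floating-point expressions on both sides), not approximately. Ports for
fixture HTTP servers are ephemeral (OS-assigned) to avoid collisions.

## Known limitations

- RDFa support is the Lite subset; full RDFa chaining/`inlist` semantics
  are not implemented. Microdata `itemref` is unsupported; itemid-less
  items yield blank nodes, so only counts should be asserted for them.
- No content negotiation: a URL is assessed by its HTML body (or given as
  a dump), not by alternate RDF representations it might serve.
- `sameAs`-based identity reasoning is not performed during enrichment.
- The vocabulary catalogs are namespace-level snapshots, not live
  registry mirrors; a term in a known namespace but absent from the real
  registry would still count as known offline.
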
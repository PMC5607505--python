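# Methods

## Problem setting

Bioinformatics entities — protein targets, bioassays, cell lines,
publications — are published as RDF at many independent endpoints, under
different URIs and vocabularies. Two needs drive this package: querying
several such sources at once from a single keyword, and recognising when
URIs returned by different sources denote the same entity.

## Registry model

The registry is an RDF document in a single project namespace
(`https://w3id.org/fedsim/datasources#`). Topics own subtopics
(`hasSubTopic`); subtopics own templates (`hasTemplate`); templates are
connected to dataset descriptors (`connectedWith`; the historical spelling
`conectedWith` is accepted on load). A template carries a small integer
label, a human-readable name, the keyword kind it accepts (InChIKey,
SMILES or unrestricted — the variants "InChiKey", "SMILE" and "No
restriction" are normalised on load), the SPARQL variable it binds, a
similarity-enabled flag, and its predefined query (`hasInitialQuery`).
A dataset descriptor carries name, initiative, endpoint URL, dataset
link, comment, a pattern-query fragment and the set of selected
predicates.

Two pragmatic additions keep round trips exact without blank nodes:
a `datasetOrder` literal records per-template source order (RDF triples
are unordered), and a `linkPattern` literal stores a template-specific
pattern fragment when a dataset serves several templates with different
result variables (e.g. the laboratory dataset binds `?Target` for the
targets template but `?Assay` for the assay template). Loading sorts
topics by name, templates by label and datasets by (name, initiative),
so `load(save(r)) == r` field-for-field.

All registry operations are value-style: `register_dataset` returns an
updated copy and never mutates its input; persistence is explicit.

## Query construction

A template's predefined query is assembled from its datasets' pattern
fragments: each fragment becomes a `SERVICE SILENT <endpoint> { ... }`
block, blocks are combined with UNION, and a final `%s` is reserved for
an added dataset. UNION (rather than join) combination is deliberate:
each source contributes rows independently, sources may legitimately be
empty, and per-source provenance is preserved — no deduplication, no join
optimisation.

Placeholders are positional `%s` tokens inside double-quoted literals.
On instantiation every non-tail placeholder receives the keyword with
backslash, quote, newline, carriage-return and tab escaped, so hostile
input cannot break out of the literal. The tail becomes the added
dataset's SERVICE block (its own placeholders also take the keyword) or
the empty string. An added dataset's pattern must bind the template's
result variable, mirroring the registry-side validation. Every generated
text is checked against the SPARQL 1.1 grammar before being returned.

Star-shaped filter queries take one anchor triple pattern (subject =
the template's result variable) plus k selected properties, each with a
deterministic fresh object variable `?o1..?ok`, giving exactly k+1
triple patterns on one subject; the arity is verified by counting triple
patterns in the parsed algebra. The anchor is required to be a single
triple pattern so the k+1 invariant holds exactly; the CLI derives a
default anchor from the dataset's first selected predicate.

## Federated execution

A source binding maps each (dataset, initiative) to either a remote
SPARQL endpoint (HTTP POST, SPARQL-Results JSON) or a local RDF graph
file queried in process with rdflib. Sources are executed one at a time
in query order: each source's pattern fragment runs as a standalone
SELECT of the result variable, so execution matches the UNION semantics
of the assembled text. An unreachable source (missing or unparsable
file, connection error, timeout — default 30 s) yields zero rows and one
warning; results with a dead source equal results with that source
omitted. Per-source counts are maintained alongside the rows and always
sum to the row total.

## Similar-data-item detection

Only URI-valued rows enter detection (literal rows are skipped with a
notice). Each URI's profile — all its (predicate, object) pairs at the
source that returned it — is reduced to the literal object values of that
source's selected predicates, order-stable and deduplicated. The
no-restriction comparison mode (`mode="all"`) passes every literal value
instead, and exists to demonstrate why selection matters: incidental
shared values such as a common source organism dominate otherwise
dissimilar entities.

Each string is transformed: lowercase; tokens are maximal `[a-z0-9]+`
runs (hyphens, parentheses and non-ASCII characters separate tokens, so
"(MK2)" yields `mk2` and "THP-1" yields `thp`, `1`); stop words are
removed **before** stemming (a fixed ~50-entry English function-word and
pronoun list shipped with the package — checking stops after stemming
would let stems collide with function words and inflate similarity);
each surviving token is passed through the Porter (1980) stemmer,
implemented in `fedsim._porter` from the published algorithm (tokens of
length ≤ 2 and digit-bearing tokens pass through where no rule applies).

A transformed string becomes a **binary** term-presence vector; the
cosine of two vectors is the shared-term count over √(|v₁|·|v₂|)
(computed as one square root of the size product so identical sets score
exactly 1.0). Binary presence, not term frequency, is the normative
weighting: with raw frequencies the repeated token *kinas* in
"MAP kinase-activated protein kinase 2" shifts its score against
"MAPK-activated protein kinase 2" from 0.800000 to 5/√40 ≈ 0.7906,
breaking agreement with the reference values; a frequency mode is kept
behind `weighting="tf"` for exactly this comparison.

For each unordered URI pair, all cross-product string pairs are scored;
cosines at or above the threshold (default 0.7, configurable in (0, 1])
are recorded and summed into the pair aggregate. URIs are ranked by the
sum of their qualifying pair aggregates, descending; per-URI sums use
`math.fsum`, so equal contribution sets give exactly equal totals
regardless of pair enumeration order, and ties are then broken by input
order. URIs in no qualifying pair are excluded. Raising the threshold
can only remove contributions and ranked URIs (monotonicity), and the
ranking's content is invariant under input permutation.

## Fixture generator

The fixture bundle emulates the study conditions entirely offline: six
Turtle graphs (laboratory, ChEMBL-like, BindingDB-like, DrugBank-like,
PubMed-like, and a Test graph standing in for a user-added endpoint), a
registry wiring 3 topics / 4 subtopics / 4 templates to them, and a YAML
manifest. The eight reference target entities carry their published
URIs and name/synonym object values verbatim under the per-dataset
selected predicates; drug→target/assay/cell-line link predicates are
fixture inventions in `https://w3id.org/fedsim/fixtures#`, since real
sources link molecules to targets through schemas far richer than a
desk-scale emulation needs. The reference InChIKey is linked so that a
targets run returns rows from three of the four preselected sources and
none from the DrugBank-like source; the Test dataset adds two more
targets, for eight result URIs in total. Generation involves no
randomness and rebuilds are byte-identical.

What the fixtures do **not** emulate: real dataset scale (millions of
triples), endpoint latency and pagination, schema drift across database
versions, and the breadth of predicates a real property-list query would
return. Passing tests therefore validate the algorithmic pipeline and
its contracts, not retrieval quality against live public endpoints.

## Numerical and design choices

* Threshold 0.7 by default; strictly positive, at most 1.
* Aggregates and rank keys via `math.fsum`; no rounding inside the
  pipeline (the CLI prints six decimals).
* Timeout 30 s per source; a timed-out source counts as down.
* Rows are ordered by (source order in query, source-returned order);
  profile pairs are sorted by (predicate, object) for determinism.
* Similarity is enabled by default for biology/chemogenomics templates
  and disabled for the publications template, where results are
  bibliographic strings rather than entity URIs.
* Exit codes: 0 success (warnings allowed), 1 usage/configuration error,
  2 query-generation error.

## Known limitations

* The Porter stemmer is the original 1980 algorithm, not the later
  Porter2/Snowball revision; stems like *kinas* or *activ* are not
  English words and are not meant to be.
* Entity resolution is purely lexical: synonyms sharing no stemmed token
  (e.g. "MAPKAPK-2" vs "MAPKAP kinase 2" after tokenization) can fall
  below threshold even when the entities are identical; conversely,
  lexically close but biologically distinct kinase names can exceed it.
* The remote-endpoint client covers plain SPARQL Protocol POST with JSON
  results; no authentication, caching or result pagination.
* No OWL reasoning over the registry; it is validated structurally.
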
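# fedsim

Ontology-driven construction and execution of **federated SPARQL queries**
over multiple bioinformatics datasets, with detection of **similar data
items** — URIs at different endpoints that denote the same real-world
entity (a protein target, an assay, a cell line).

It is built for bench and dry-lab researchers in drug discovery who need
to pre-screen a synthesized compound across siloed linked-data sources
(a local laboratory dataset plus ChEMBL-, BindingDB-, DrugBank- and
PubMed-style endpoints) without writing SPARQL: a query is picked by
topic, subtopic and template ("Find targets for the drug") and driven by a
single keyword (InChIKey, SMILES, or free text).

## What it does

* **Registry** (`fedsim.registry`) — an RDF (Turtle) document describing
  topics, subtopics, templates, datasets, endpoints, per-dataset pattern
  queries, and the predicates selected for similarity. Loaded, validated,
  edited (user datasets can be registered against a template) and saved
  round-trip.
* **Query generation** (`fedsim.querygen`) — templates hold a predefined
  federated query with positional `%s` placeholders; all but the last take
  the (escaped) keyword, the last is reserved for an added dataset's
  SERVICE block. Also: star-shaped filter queries (one subject variable,
  *k* joins, hence *k*+1 triple patterns), per-URI profile queries, and
  per-dataset property-list queries.
* **Federation** (`fedsim.federation`) — each source is executed
  independently (`SERVICE SILENT` semantics) against a remote endpoint or
  a local RDF graph file; rows are tagged with dataset and initiative, a
  dead source contributes zero rows plus a warning, and per-source counts
  always sum to the row total.
* **Similarity** (`fedsim.similarity`) — the detection algorithm:

  1. for each URI in the result set, fetch its (predicate, object) pairs
     and keep the literal values of the expert-selected predicates;
  2. normalise each string: lowercase, tokenize on `[a-z0-9]+` runs,
     remove stop words, Porter-stem each token;
  3. represent each string as a binary term-presence vector **v** and
     compare pairs with the cosine similarity measure

     cos(v₁, v₂) = |v₁ ∩ v₂| / ( √|v₁| · √|v₂| )

  4. cosines ≥ 0.7 (configurable) are summed per unordered URI pair, and
     URIs are ranked by their total over all qualifying pairs.

* **Fixtures** (`fedsim.fixtures`) — a deterministic, fully offline bundle
  of six local Turtle graphs + registry + manifest that emulates the
  multi-endpoint setup, including eight reference protein-target entities
  whose name/synonym values form a worked example.

## Worked example

```console
$ fedsim make-fixtures --out demo
$ fedsim run --registry demo/registry.ttl --local-map demo/manifest.yaml \
    --topic Biology --subtopic Targets --template 1 \
    --keyword AAAAKTROWFNLEP-UHFFFAOYSA-N --stats
value	dataset	initiative
http://cpctas-lcmb.pmf.kg.ac.rs/2012/3/PIBAS#TaregtTest1	PIBAS	CPCTAS
http://rdf.ebi.ac.uk/resource/ChEMBL/target/CHEMBL2208	ChEMBL	EMBL-EBI
http://rdf.ebi.ac.uk/resource/ChEMBL/target/CHEMBL3587	ChEMBL	EMBL-EBI
http://rdf.ebi.ac.uk/resource/ChEMBL/target/CHEMBL4040	ChEMBL	EMBL-EBI
http://rdf.ebi.ac.uk/resource/ChEMBL/target/CHEMBL614245	ChEMBL	EMBL-EBI
http://chem2bio2rdf.org/bindingdb/resource/bindingdb_interaction/55299	BindingDB	Chem2Bio2RDF

# per-source counts
# PIBAS/CPCTAS	1
# ChEMBL/EMBL-EBI	4
# BindingDB/Chem2Bio2RDF	1
# Drugbank/Bio2RDF	0
```

Six targets are found in three of the four preselected sources (the
DrugBank-like source holds no entry for this InChIKey and contributes
zero rows). Adding the user-supplied Test dataset and asking for similar
data items:

```console
$ fedsim detect-similar --registry demo/registry.ttl --local-map demo/manifest.yaml \
    --topic Biology --subtopic Targets --template 1 \
    --keyword AAAAKTROWFNLEP-UHFFFAOYSA-N --add-dataset test-dataset.yaml
# ranked URIs
1	http://cpctas-lcmb.pmf.kg.ac.rs/2012/3/PIBAS#TaregtTest1
2	http://147.91.205.66:2020/Tests/TestOntology#TestTarget1
3	http://chem2bio2rdf.org/bindingdb/resource/bindingdb_interaction/55299
4	http://rdf.ebi.ac.uk/resource/ChEMBL/target/CHEMBL2208
# pair scores
uri_a	uri_b	string_a	string_b	cosine
...#TaregtTest1	...CHEMBL2208	MAPK-activated protein kinase 2	MAP kinase-activated protein kinase 2	0.800000
...#TaregtTest1	...55299	MAPK-activated protein kinase 2	MAPK-Activated Protein Kinase 2 (MK2)	0.912871
...#TaregtTest1	...#TestTarget1	MAPK-activated protein kinase 2	MAPK-activated protein kinase 2	1.000000
...CHEMBL2208	...55299	MAP kinase-activated protein kinase 2	MAPK-Activated Protein Kinase 2 (MK2)	0.730297
...CHEMBL2208	...#TestTarget1	MAP kinase-activated protein kinase 2	MAPK-activated protein kinase 2	0.800000
...55299	...#TestTarget1	MAPK-Activated Protein Kinase 2 (MK2)	MAPK-activated protein kinase 2	0.912871
```

(URI columns abbreviated here for width; `test-dataset.yaml` is the
added-dataset descriptor — name, initiative, endpoint URL, pattern query
binding `?Target`, selected predicates.) Four of the eight returned URIs
are variants of MAPK-activated protein kinase 2 under different
identifiers; the two unrelated targets, the THP-1 entry and the
HPr protein never reach the 0.7 threshold and are excluded. Exact string
duplicates score 1.0; `--threshold 1.0` would keep only those.

`--mode all-predicates` disables predicate selection for comparison: the
shared organism name *Homo sapiens* then pulls all ChEMBL entities into
the ranking, which is precisely why expert predicate selection is the
default.

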
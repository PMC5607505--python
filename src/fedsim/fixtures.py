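"""Offline fixture bundle: local RDF graphs plus a registry document.

The bundle emulates the full multi-endpoint setup on local Turtle files so
that every feature — predefined federated queries, dataset addition, star
filtering, similar-data-item detection — runs with no network:

* a PIBAS-like laboratory graph, ChEMBL-like, BindingDB-like and
  Drugbank-like graphs, a PubMed-like publications graph and a small Test
  graph standing in for a user-added endpoint;
* a registry document with 3 topics, 4 subtopics and 4 templates
  (targets / assays / cell lines / papers) wired to those graphs;
* a YAML manifest mapping each dataset to its graph file.

The target graphs hold eight protein-target entities whose name/synonym
object values under the per-dataset selected predicates form the reference
working example for similarity detection.  Entity URIs and the selected
predicates reproduce the published sources they emulate; link predicates
tying drugs to targets/assays/cell lines are fixture inventions in the
``https://w3id.org/fedsim/fixtures#`` namespace.

Output is deterministic: rebuilding the bundle yields identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml
from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef

from . import querygen
from .federation import SourceBinding
from .registry import (
    DatasetSpec,
    Registry,
    Subtopic,
    Template,
    Topic,
    save_registry,
)

__all__ = [
    "CANONICAL_INCHIKEY",
    "FIXTURE_URIS",
    "FixtureBundle",
    "build_fixture_bundle",
    "build_drug_link_fixture",
    "build_registry",
    "local_bindings",
    "test_dataset_spec",
]

FX = Namespace("https://w3id.org/fedsim/fixtures#")
PIBAS = Namespace("http://cpctas-lcmb.pmf.kg.ac.rs/2012/3/PIBAS#")
CHEMBL_TARGET = "http://rdf.ebi.ac.uk/resource/ChEMBL/target/"
CHEMBL_TERMS = Namespace("http://rdf.ebi.ac.uk/terms/chembl#")
BDB = "http://chem2bio2rdf.org/bindingdb/resource/"
TEST = Namespace("http://147.91.205.66:2020/Tests/TestOntology#")
DCT = Namespace("http://purl.org/dc/terms/")

#: InChIKey of the working-example drug.
CANONICAL_INCHIKEY = "AAAAKTROWFNLEP-UHFFFAOYSA-N"
#: SMILES keyword used by the assay/cell-line fixtures (aspirin).
CANONICAL_SMILES = "CC(=O)Oc1ccccc1C(=O)O"

#: The eight working-example entities, in result-set order.
FIXTURE_URIS = {
    "URI_1": str(PIBAS.TaregtTest1),
    "URI_2": CHEMBL_TARGET + "CHEMBL2208",
    "URI_3": CHEMBL_TARGET + "CHEMBL3587",
    "URI_4": CHEMBL_TARGET + "CHEMBL4040",
    "URI_5": CHEMBL_TARGET + "CHEMBL614245",
    "URI_6": BDB + "bindingdb_interaction/55299",
    "URI_7": str(TEST.TestTarget1),
    "URI_8": str(TEST.TestTarget2),
}

_CHEMBL_LABELS = {
    "CHEMBL2208": "MAP kinase-activated protein kinase 2",
    "CHEMBL3587": "Dual specificity mitogen-activated protein kinase kinase 1",
    "CHEMBL4040": "MAP kinase ERK2",
    "CHEMBL614245": "THP-1",
}


@dataclass
class FixtureBundle:
    """Paths of a built fixture bundle."""

    directory: Path
    registry_path: Path
    graph_paths: dict[str, Path]  # dataset qualified name -> turtle file
    manifest_path: Path


def _pibas_spec() -> DatasetSpec:
    return DatasetSpec(
        name="PIBAS",
        initiative="CPCTAS",
        endpoint_url="http://cpctas-lcmb.pmf.kg.ac.rs:2020/sparql",
        dataset_link="http://cpctas-lcmb.pmf.kg.ac.rs/2012/3/PIBAS",
        comment="Local laboratory dataset of bioactive-substance experiments",
        pattern_query=(
            f'?drug <{FX.inchiKey}> "%s" .\n'
            f"?drug <{FX.hasTarget}> ?Target ."
        ),
        selected_predicates=frozenset(
            {str(PIBAS.hasTargetName), str(PIBAS.hasSynonym)}
        ),
    )


def _chembl_spec() -> DatasetSpec:
    return DatasetSpec(
        name="ChEMBL",
        initiative="EMBL-EBI",
        endpoint_url="https://www.ebi.ac.uk/rdf/services/sparql",
        dataset_link="https://www.ebi.ac.uk/chembl/",
        comment="Bioactive molecules and their targets",
        pattern_query=(
            f'?drug <{FX.inchiKey}> "%s" .\n'
            f"?drug <{FX.hasTarget}> ?Target ."
        ),
        selected_predicates=frozenset({str(RDFS.label)}),
    )


def _bindingdb_spec() -> DatasetSpec:
    return DatasetSpec(
        name="BindingDB",
        initiative="Chem2Bio2RDF",
        endpoint_url="http://chem2bio2rdf.org/bindingdb/sparql",
        dataset_link="https://www.bindingdb.org/bind/index.jsp",
        comment="Measured binding affinities; rows are interactions",
        pattern_query=f'?Target <{FX.inchiKey}> "%s" .',
        selected_predicates=frozenset({BDB + "TARGET"}),
    )


def _drugbank_spec() -> DatasetSpec:
    return DatasetSpec(
        name="Drugbank",
        initiative="Bio2RDF",
        endpoint_url="http://drugbank.bio2rdf.org/sparql",
        dataset_link="http://www.drugbank.ca/",
        comment="Drug and drug-target resource",
        pattern_query=(
            f'?drug <{FX.inchiKey}> "%s" .\n'
            f"?drug <{FX.hasTarget}> ?Target ."
        ),
        selected_predicates=frozenset({str(DCT.title), str(RDFS.label)}),
    )


def _pubmed_spec() -> DatasetSpec:
    return DatasetSpec(
        name="PubMed",
        initiative="Bio2RDF",
        endpoint_url="http://pubmed.bio2rdf.org/sparql",
        dataset_link="http://www.ncbi.nlm.nih.gov/pubmed/",
        comment="Publication metadata",
        pattern_query=(
            f"?Paper <{DCT.title}> ?title0 .\n"
            'FILTER(CONTAINS(LCASE(STR(?title0)), LCASE("%s")))'
        ),
        selected_predicates=frozenset({str(DCT.title)}),
    )


def test_dataset_spec() -> DatasetSpec:
    """Descriptor of the user-added Test dataset (not in the registry)."""
    return DatasetSpec(
        name="Test",
        initiative="TestInitiative",
        endpoint_url="http://147.91.205.66:2020/Tests/sparql",
        dataset_link="http://147.91.205.66:2020/Tests",
        comment="Test dataset with a test ontology and a test endpoint",
        pattern_query=(
            f'?drug <{TEST.hasInChiKey}> "%s" .\n'
            f"?drug <{TEST.hasTarget}> ?Target ."
        ),
        selected_predicates=frozenset(
            {str(TEST.hasSynonym), str(TEST.hasName)}
        ),
    )


def _assay_pattern() -> str:
    return (
        f'?drug <{FX.smiles}> "%s" .\n'
        f"?drug <{FX.hasAssay}> ?Assay ."
    )


def _cellline_pattern() -> str:
    return (
        f'?drug <{FX.inchiKey}> "%s" .\n'
        f"?drug <{FX.hasCellLine}> ?CellLine ."
    )


def build_registry() -> Registry:
    """The fixture registry: 3 topics, 4 subtopics, 4 templates.

    Template labels and keyword kinds: 1 targets/InChIKey, 2 assays/SMILES,
    3 cell lines/InChIKey, 4 papers/unrestricted.  Similarity detection is
    enabled for the Biology and Chemogenomic templates and disabled for
    Research.
    """
    pibas = _pibas_spec()
    chembl = _chembl_spec()
    bindingdb = _bindingdb_spec()
    drugbank = _drugbank_spec()
    pubmed = _pubmed_spec()

    t1_datasets = [pibas, chembl, bindingdb, drugbank]
    t1 = Template(
        label=1,
        name="Find targets for the drug",
        keyword_kind="InChIKey",
        result_variable="Target",
        initial_query_pattern=querygen.assemble_initial_query("Target", t1_datasets),
        similarity_enabled=True,
        connected_datasets=t1_datasets,
    )

    def variant(ds: DatasetSpec, pattern: str) -> DatasetSpec:
        return replace(ds, pattern_query=pattern)

    t2_datasets = [variant(pibas, _assay_pattern()),
                   variant(chembl, _assay_pattern())]
    t2 = Template(
        label=2,
        name="Find assays for the drug",
        keyword_kind="SMILES",
        result_variable="Assay",
        initial_query_pattern=querygen.assemble_initial_query("Assay", t2_datasets),
        similarity_enabled=True,
        connected_datasets=t2_datasets,
    )

    t3_datasets = [variant(pibas, _cellline_pattern()),
                   variant(chembl, _cellline_pattern())]
    t3 = Template(
        label=3,
        name="Find cell lines for the drug",
        keyword_kind="InChIKey",
        result_variable="CellLine",
        initial_query_pattern=querygen.assemble_initial_query("CellLine", t3_datasets),
        similarity_enabled=True,
        connected_datasets=t3_datasets,
    )

    t4_datasets = [pubmed]
    t4 = Template(
        label=4,
        name="Find papers with a title for the keyword",
        keyword_kind="unrestricted",
        result_variable="Paper",
        initial_query_pattern=querygen.assemble_initial_query("Paper", t4_datasets),
        similarity_enabled=False,
        connected_datasets=t4_datasets,
    )

    # the registry-wide dataset collection is keyed by (name, initiative):
    # per-template variants reuse the same keys, so register each key once
    # with the template-1 pattern (templates carry their own variants).
    datasets = [pibas, chembl, bindingdb, drugbank, pubmed]
    return Registry(
        topics=[
            Topic(name="Biology", subtopics=[Subtopic(name="Targets", templates=[t1])]),
            Topic(
                name="Chemogenomic",
                subtopics=[
                    Subtopic(name="Assays", templates=[t2]),
                    Subtopic(name="Cell lines", templates=[t3]),
                ],
            ),
            Topic(name="Research", subtopics=[Subtopic(name="Papers", templates=[t4])]),
        ],
        datasets=sorted(datasets, key=lambda d: d.key),
    )


def _pibas_graph() -> Graph:
    g = Graph()
    g.bind("pibas", PIBAS)
    g.bind("fx", FX)
    target = URIRef(FIXTURE_URIS["URI_1"])
    g.add((target, RDF.type, PIBAS.Target))
    g.add((target, PIBAS.hasTargetName, Literal("MAPKAP kinase 2")))
    g.add((target, PIBAS.hasSynonym, Literal("MAPK-activated protein kinase 2")))
    assay = PIBAS.Assay1
    g.add((assay, RDF.type, PIBAS.Assay))
    g.add((assay, PIBAS.hasAssayName, Literal("MTT cytotoxicity assay")))
    cell = PIBAS.CellLine1
    g.add((cell, RDF.type, PIBAS.CellLine))
    g.add((cell, PIBAS.hasCellLineName, Literal("HCT-116")))
    return g


def _chembl_graph() -> Graph:
    g = Graph()
    g.bind("rdfs", RDFS)
    g.bind("cco", CHEMBL_TERMS)
    for chembl_id, label in _CHEMBL_LABELS.items():
        node = URIRef(CHEMBL_TARGET + chembl_id)
        g.add((node, RDF.type, CHEMBL_TERMS.SingleProtein))
        g.add((node, RDFS.label, Literal(label)))
        g.add((node, CHEMBL_TERMS.organismName, Literal("Homo sapiens")))
    assay = URIRef("http://rdf.ebi.ac.uk/resource/ChEMBL/assay/CHEMBL615156")
    g.add((assay, RDF.type, CHEMBL_TERMS.Assay))
    g.add((assay, RDFS.label, Literal("Cytotoxicity against human THP-1 cells")))
    cell = URIRef("http://rdf.ebi.ac.uk/resource/ChEMBL/cell_line/CHEMBL3307525")
    g.add((cell, RDF.type, CHEMBL_TERMS.CellLine))
    g.add((cell, RDFS.label, Literal("THP-1")))
    return g


def _bindingdb_graph() -> Graph:
    g = Graph()
    g.bind("bdb", Namespace(BDB))
    node = URIRef(FIXTURE_URIS["URI_6"])
    g.add((node, URIRef(BDB + "TARGET"),
           Literal("MAPK-Activated Protein Kinase 2 (MK2)")))
    g.add((node, URIRef(BDB + "CID_GENE"), Literal("MAPKAPK2")))
    g.add((node, URIRef(BDB + "uniprot"), Literal("P49137")))
    return g


def _drugbank_graph() -> Graph:
    g = Graph()
    g.bind("dct", DCT)
    g.bind("fx", FX)
    drug = URIRef("http://bio2rdf.org/drugbank:DB00945")
    g.add((drug, RDF.type, URIRef("http://bio2rdf.org/drugbank_vocabulary:Drug")))
    g.add((drug, DCT.title, Literal("Acetylsalicylic acid")))
    g.add((drug, FX.inchiKey, Literal("BSYNRYMUTXBXSQ-UHFFFAOYSA-N")))
    target = URIRef("http://bio2rdf.org/drugbank_target:3829")
    g.add((drug, FX.hasTarget, target))
    g.add((target, DCT.title, Literal("Prostaglandin G/H synthase 1")))
    g.add((target, RDFS.label, Literal("Prostaglandin G/H synthase 1")))
    return g


def _pubmed_graph() -> Graph:
    g = Graph()
    g.bind("dct", DCT)
    papers = {
        "pubmed:24441586": "MAPK-activated protein kinase 2 in inflammation",
        "pubmed:19565474": "Histidine-containing phosphocarrier protein function",
    }
    for frag, title in papers.items():
        node = URIRef("http://bio2rdf.org/" + frag)
        g.add((node, DCT.title, Literal(title)))
    return g


def _test_graph() -> Graph:
    g = Graph()
    g.bind("test", TEST)
    t1 = URIRef(FIXTURE_URIS["URI_7"])
    g.add((t1, RDF.type, TEST.Target))
    g.add((t1, TEST.hasName, Literal("MAPKAPK-2")))
    g.add((t1, TEST.hasSynonym, Literal("MAPK-activated protein kinase 2")))
    t2 = URIRef(FIXTURE_URIS["URI_8"])
    g.add((t2, RDF.type, TEST.Target))
    g.add((t2, TEST.hasName, Literal("Histidine-containing protein")))
    g.add((t2, TEST.hasSynonym, Literal("Phosphocarrier protein HPr")))
    return g


def build_drug_link_fixture(
    graphs: dict[str, Graph], keyword: str = CANONICAL_INCHIKEY
) -> None:
    """Add drug-to-item link triples for ``keyword`` to the graphs in place.

    Links are laid out so that a targets query for the keyword returns rows
    from the PIBAS-like, ChEMBL-like, BindingDB-like and Test graphs but
    none from the Drugbank-like graph.
    """
    suffix = "".join(c for c in keyword if c.isalnum())[:24] or "Drug"

    g = graphs["PIBAS/CPCTAS"]
    drug = PIBAS["Drug_" + suffix]
    g.add((drug, FX.inchiKey, Literal(keyword)))
    g.add((drug, FX.smiles, Literal(CANONICAL_SMILES)))
    g.add((drug, FX.hasTarget, URIRef(FIXTURE_URIS["URI_1"])))
    g.add((drug, FX.hasAssay, PIBAS.Assay1))
    g.add((drug, FX.hasCellLine, PIBAS.CellLine1))

    g = graphs["ChEMBL/EMBL-EBI"]
    drug = URIRef("http://rdf.ebi.ac.uk/resource/ChEMBL/molecule/Drug_" + suffix)
    g.add((drug, FX.inchiKey, Literal(keyword)))
    g.add((drug, FX.smiles, Literal(CANONICAL_SMILES)))
    for chembl_id in _CHEMBL_LABELS:
        g.add((drug, FX.hasTarget, URIRef(CHEMBL_TARGET + chembl_id)))
    g.add((drug, FX.hasAssay,
           URIRef("http://rdf.ebi.ac.uk/resource/ChEMBL/assay/CHEMBL615156")))
    g.add((drug, FX.hasCellLine,
           URIRef("http://rdf.ebi.ac.uk/resource/ChEMBL/cell_line/CHEMBL3307525")))

    g = graphs["BindingDB/Chem2Bio2RDF"]
    g.add((URIRef(FIXTURE_URIS["URI_6"]), FX.inchiKey, Literal(keyword)))

    g = graphs["Test/TestInitiative"]
    drug = TEST["Drug_" + suffix]
    g.add((drug, TEST.hasInChiKey, Literal(keyword)))
    g.add((drug, TEST.hasTarget, URIRef(FIXTURE_URIS["URI_7"])))
    g.add((drug, TEST.hasTarget, URIRef(FIXTURE_URIS["URI_8"])))


_GRAPH_FILES = {
    "PIBAS/CPCTAS": "pibas.ttl",
    "ChEMBL/EMBL-EBI": "chembl.ttl",
    "BindingDB/Chem2Bio2RDF": "bindingdb.ttl",
    "Drugbank/Bio2RDF": "drugbank.ttl",
    "PubMed/Bio2RDF": "pubmed.ttl",
    "Test/TestInitiative": "test.ttl",
}


def build_fixture_bundle(output_dir: str | Path) -> FixtureBundle:
    """Write the registry, the six graphs and the manifest to ``output_dir``.

    Deterministic: no randomness, sorted serialisations, byte-stable across
    rebuilds.
    """
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write-probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"fixture directory {out} is not writable: {exc}") from exc

    graphs = {
        "PIBAS/CPCTAS": _pibas_graph(),
        "ChEMBL/EMBL-EBI": _chembl_graph(),
        "BindingDB/Chem2Bio2RDF": _bindingdb_graph(),
        "Drugbank/Bio2RDF": _drugbank_graph(),
        "PubMed/Bio2RDF": _pubmed_graph(),
        "Test/TestInitiative": _test_graph(),
    }
    build_drug_link_fixture(graphs, CANONICAL_INCHIKEY)

    graph_paths: dict[str, Path] = {}
    for key, graph in graphs.items():
        path = out / _GRAPH_FILES[key]
        path.write_text(graph.serialize(format="turtle"), encoding="utf-8")
        graph_paths[key] = path

    registry_path = out / "registry.ttl"
    save_registry(build_registry(), registry_path)

    manifest = {
        "datasets": {key: _GRAPH_FILES[key] for key in sorted(_GRAPH_FILES)},
        "registry": "registry.ttl",
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(
        yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8"
    )
    return FixtureBundle(
        directory=out,
        registry_path=registry_path,
        graph_paths=graph_paths,
        manifest_path=manifest_path,
    )


def local_bindings(bundle_dir: str | Path) -> list[SourceBinding]:
    """Source bindings pointing every fixture dataset at its local graph."""
    base = Path(bundle_dir)
    manifest = yaml.safe_load((base / "manifest.yaml").read_text(encoding="utf-8"))
    bindings = []
    for key, filename in manifest["datasets"].items():
        name, initiative = key.split("/", 1)
        bindings.append(
            SourceBinding(
                dataset=name,
                initiative=initiative,
                graph_path=str(base / filename),
            )
        )
    return bindings
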
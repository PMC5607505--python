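"""Data-source registry: topics, subtopics, templates and dataset descriptors.

The registry is an RDF document (Turtle on save; Turtle or RDF/XML on load)
using a small project vocabulary rooted at
``https://w3id.org/fedsim/datasources#``.  It drives all query construction:
a *template* is a parameterized federated query ("Find targets for the
drug") nested under a subtopic and topic, connected to one or more *dataset
descriptors* via ``connectedWith`` (the historical spelling ``conectedWith``
is accepted on load).  Each dataset descriptor carries the endpoint URL, a
SPARQL graph-pattern fragment with ``%s`` keyword placeholders, and the set
of predicates whose object values feed similar-data-item detection.

Registry operations are value-style: they return updated copies and leave
their input untouched; persistence is explicit via :func:`save_registry`.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

from rdflib import Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import XSD

from .querygen import QueryPattern

__all__ = [
    "FEDSIM",
    "DatasetSpec",
    "Registry",
    "RegistryFormatError",
    "RegistryValidationError",
    "Subtopic",
    "Template",
    "Topic",
    "load_registry",
    "register_dataset",
    "resolve_template",
    "save_registry",
]

FEDSIM = Namespace("https://w3id.org/fedsim/datasources#")

KEYWORD_KINDS = ("InChIKey", "SMILES", "unrestricted")

# spelling variants seen in source material, normalised on load
_KIND_ALIASES = {
    "inchikey": "InChIKey",
    "inchi key": "InChIKey",
    "smile": "SMILES",
    "smiles": "SMILES",
    "no restriction": "unrestricted",
    "unrestricted": "unrestricted",
}

_KNOWN_PREDICATES = {
    FEDSIM.hasSubTopic, FEDSIM.hasTemplate, FEDSIM.connectedWith,
    FEDSIM.conectedWith, FEDSIM.hasInitialQuery, FEDSIM.templateLabel,
    FEDSIM.templateName, FEDSIM.keywordKind, FEDSIM.resultVariable,
    FEDSIM.similarityEnabled, FEDSIM.tailReserved, FEDSIM.datasetName,
    FEDSIM.initiative, FEDSIM.endpointURL, FEDSIM.datasetLink,
    FEDSIM.comment, FEDSIM.patternQuery, FEDSIM.selectedPredicate,
    FEDSIM.topicName, FEDSIM.subtopicName, FEDSIM.datasetOrder,
    FEDSIM.linkPattern, RDF.type,
}


class RegistryFormatError(ValueError):
    """The document does not parse as RDF in a supported syntax."""


class RegistryValidationError(ValueError):
    """The document parses but violates a registry invariant."""


class RegistryLookupError(LookupError):
    """A requested topic/subtopic/template does not exist."""


class RegistryConsistencyError(RegistryLookupError):
    """Topic/subtopic/template names exist but are not nested as requested."""


@dataclass(frozen=True)
class DatasetSpec:
    """Descriptor of one RDF dataset within an initiative.

    ``pattern_query`` is the SPARQL graph-pattern fragment contributed to
    federated queries (with ``%s`` keyword placeholders); when the dataset
    is connected to a template it must bind the template's result variable.
    ``selected_predicates`` are the predicate URIs whose object values are
    used by similarity detection.
    """

    name: str
    initiative: str
    endpoint_url: str
    dataset_link: str = ""
    comment: str = ""
    pattern_query: str = ""
    selected_predicates: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, str]:
        return (self.name, self.initiative)

    @property
    def qualified_name(self) -> str:
        return f"{self.name}/{self.initiative}"


@dataclass
class Template:
    """A predefined federated query taking one keyword."""

    label: int
    name: str
    keyword_kind: str
    result_variable: str
    initial_query_pattern: QueryPattern
    similarity_enabled: bool = True
    connected_datasets: list[DatasetSpec] = field(default_factory=list)


@dataclass
class Subtopic:
    name: str
    templates: list[Template] = field(default_factory=list)


@dataclass
class Topic:
    name: str
    subtopics: list[Subtopic] = field(default_factory=list)


@dataclass
class Registry:
    """The full data-source registry held in memory."""

    topics: list[Topic] = field(default_factory=list)
    datasets: list[DatasetSpec] = field(default_factory=list)

    def templates(self) -> list[Template]:
        return [
            t
            for topic in self.topics
            for sub in topic.subtopics
            for t in sub.templates
        ]

    def dataset(self, name: str, initiative: str) -> DatasetSpec:
        for ds in self.datasets:
            if ds.key == (name, initiative):
                return ds
        raise RegistryLookupError(f"no dataset {name}/{initiative} in registry")


def _validate(registry: Registry) -> None:
    if not registry.topics:
        raise RegistryValidationError("no topics found")
    names = [t.name for t in registry.topics]
    if len(set(names)) != len(names):
        raise RegistryValidationError(f"duplicate topic names: {sorted(names)}")
    keys = [ds.key for ds in registry.datasets]
    if len(set(keys)) != len(keys):
        raise RegistryValidationError("duplicate (name, initiative) dataset keys")
    labels: list[int] = []
    for topic in registry.topics:
        if not topic.subtopics:
            raise RegistryValidationError(f"topic {topic.name!r} has no subtopics")
        for sub in topic.subtopics:
            if not sub.templates:
                raise RegistryValidationError(
                    f"subtopic {sub.name!r} has no templates"
                )
            for t in sub.templates:
                labels.append(t.label)
                if not t.result_variable:
                    raise RegistryValidationError(
                        f"template {t.label} lacks a result variable"
                    )
                if t.initial_query_pattern is None or not t.initial_query_pattern.text:
                    raise RegistryValidationError(
                        f"template {t.label} ({t.name!r}) lacks an initial query pattern"
                    )
                if t.keyword_kind not in KEYWORD_KINDS:
                    raise RegistryValidationError(
                        f"template {t.label} has unknown keyword kind {t.keyword_kind!r}"
                    )
                if not t.connected_datasets:
                    raise RegistryValidationError(
                        f"template {t.label} is connected to no dataset"
                    )
                known = {ds.key for ds in registry.datasets}
                for ds in t.connected_datasets:
                    if ds.key not in known:
                        raise RegistryValidationError(
                            f"template {t.label} references unknown dataset "
                            f"{ds.qualified_name}"
                        )
                    if ds.pattern_query and f"?{t.result_variable}" not in ds.pattern_query:
                        raise RegistryValidationError(
                            f"pattern query of {ds.qualified_name} does not bind "
                            f"?{t.result_variable} required by template {t.label}"
                        )
    if len(set(labels)) != len(labels):
        raise RegistryValidationError(f"duplicate template labels: {sorted(labels)}")


def _normalise_kind(raw: str) -> str:
    kind = _KIND_ALIASES.get(raw.strip().lower())
    if kind is None:
        return raw
    return kind


def _node_str(graph: Graph, node, pred, default: str | None = None) -> str:
    value = graph.value(node, pred)
    if value is None:
        if default is not None:
            return default
        raise RegistryValidationError(
            f"entity {node} is missing mandatory property {pred}"
        )
    return str(value)


def _load_dataset(graph: Graph, node) -> DatasetSpec:
    return DatasetSpec(
        name=_node_str(graph, node, FEDSIM.datasetName),
        initiative=_node_str(graph, node, FEDSIM.initiative),
        endpoint_url=_node_str(graph, node, FEDSIM.endpointURL),
        dataset_link=_node_str(graph, node, FEDSIM.datasetLink, ""),
        comment=_node_str(graph, node, FEDSIM.comment, ""),
        pattern_query=_node_str(graph, node, FEDSIM.patternQuery, ""),
        selected_predicates=frozenset(
            str(p) for p in graph.objects(node, FEDSIM.selectedPredicate)
        ),
    )


def load_registry(source: Union[str, Path]) -> Registry:
    """Load and validate a registry document (Turtle or RDF/XML).

    Unknown extra triples are ignored with a warning; missing mandatory
    properties raise :class:`RegistryValidationError` naming the entity.
    """
    graph = Graph()
    data: str | None = None
    path: Path | None = None
    if isinstance(source, str) and ("\n" in source or "@prefix" in source):
        data = source
    else:
        path = Path(source)
        if not path.exists():
            raise RegistryFormatError(f"registry file not found: {source}")
    last_error: Exception | None = None
    for fmt in ("turtle", "xml"):
        try:
            fresh = Graph()
            if data is not None:
                fresh.parse(data=data, format=fmt)
            else:
                fresh.parse(str(path), format=fmt)
            graph = fresh
            last_error = None
            break
        except Exception as exc:  # rdflib raises syntax-specific errors
            last_error = exc
    if last_error is not None:
        raise RegistryFormatError(f"cannot parse registry document: {last_error}")

    unknown = {p for p in graph.predicates() if p not in _KNOWN_PREDICATES}
    if unknown:
        warnings.warn(
            f"ignoring {len(unknown)} unknown registry predicate(s): "
            + ", ".join(sorted(str(u) for u in unknown)[:5]),
            stacklevel=2,
        )

    datasets = {
        node: _load_dataset(graph, node)
        for node in sorted(graph.subjects(RDF.type, FEDSIM.Dataset))
    }

    templates: dict = {}
    for node in graph.subjects(RDF.type, FEDSIM.Template):
        label_raw = graph.value(node, FEDSIM.templateLabel)
        if label_raw is None:
            raise RegistryValidationError(f"template {node} has no label")
        pattern_text = graph.value(node, FEDSIM.hasInitialQuery)
        if pattern_text is None:
            raise RegistryValidationError(
                f"template {node} has no initial query pattern (hasInitialQuery)"
            )
        tail = graph.value(node, FEDSIM.tailReserved)
        connected_nodes = set(graph.objects(node, FEDSIM.connectedWith)) | set(
            graph.objects(node, FEDSIM.conectedWith)
        )
        connected = []
        for ds_node in connected_nodes:
            if ds_node not in datasets:
                raise RegistryValidationError(
                    f"template {node} connectedWith unknown dataset node {ds_node}"
                )
            connected.append(datasets[ds_node])
        order_raw = graph.value(node, FEDSIM.datasetOrder)
        if order_raw is not None:
            wanted = str(order_raw).split("|")
            connected.sort(
                key=lambda ds: wanted.index(ds.qualified_name)
                if ds.qualified_name in wanted
                else len(wanted)
            )
        else:
            connected.sort(key=lambda ds: ds.key)
        # a template may use a dataset with a pattern fragment specific to
        # this template (the fragment must bind the template's variable);
        # such overrides are stored on the template node
        overrides: dict[str, str] = {}
        for lit in graph.objects(node, FEDSIM.linkPattern):
            qname, _, pat = str(lit).partition("\n")
            overrides[qname] = pat
        connected = [
            replace(ds, pattern_query=overrides[ds.qualified_name])
            if ds.qualified_name in overrides
            else ds
            for ds in connected
        ]
        templates[node] = Template(
            label=int(label_raw),
            name=_node_str(graph, node, FEDSIM.templateName),
            keyword_kind=_normalise_kind(_node_str(graph, node, FEDSIM.keywordKind)),
            result_variable=_node_str(graph, node, FEDSIM.resultVariable),
            initial_query_pattern=QueryPattern(
                text=str(pattern_text),
                tail_reserved=bool(tail.toPython()) if tail is not None else True,
            ),
            similarity_enabled=(
                True if (sim := graph.value(node, FEDSIM.similarityEnabled)) is None
                else bool(sim.toPython())
            ),
            connected_datasets=connected,
        )

    topics: list[Topic] = []
    for t_node in sorted(graph.subjects(RDF.type, FEDSIM.Topic)):
        subs: list[Subtopic] = []
        for s_node in sorted(graph.objects(t_node, FEDSIM.hasSubTopic)):
            tmpl_nodes = sorted(
                graph.objects(s_node, FEDSIM.hasTemplate),
                key=lambda n: int(graph.value(n, FEDSIM.templateLabel) or 0),
            )
            subs.append(
                Subtopic(
                    name=_node_str(graph, s_node, FEDSIM.subtopicName),
                    templates=[templates[n] for n in tmpl_nodes if n in templates],
                )
            )
        subs.sort(key=lambda s: min((t.label for t in s.templates), default=0))
        topics.append(Topic(name=_node_str(graph, t_node, FEDSIM.topicName), subtopics=subs))
    topics.sort(key=lambda t: t.name)

    registry = Registry(topics=topics, datasets=sorted(datasets.values(), key=lambda d: d.key))
    _validate(registry)
    return registry


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in text)


def save_registry(registry: Registry, destination: Union[str, Path, None] = None) -> str:
    """Serialise a registry to Turtle; optionally write it to ``destination``.

    Round-trips: ``load_registry(save_registry(r))`` equals ``r``
    field-for-field for any registry produced by :func:`load_registry` or
    the fixture builder.
    """
    _validate(registry)
    graph = Graph()
    graph.bind("ds", FEDSIM)

    ds_nodes: dict[tuple[str, str], URIRef] = {}
    for ds in registry.datasets:
        node = FEDSIM[f"Dataset_{_slug(ds.name)}_{_slug(ds.initiative)}"]
        ds_nodes[ds.key] = node
        graph.add((node, RDF.type, FEDSIM.Dataset))
        graph.add((node, FEDSIM.datasetName, Literal(ds.name)))
        graph.add((node, FEDSIM.initiative, Literal(ds.initiative)))
        graph.add((node, FEDSIM.endpointURL, Literal(ds.endpoint_url)))
        if ds.dataset_link:
            graph.add((node, FEDSIM.datasetLink, Literal(ds.dataset_link)))
        if ds.comment:
            graph.add((node, FEDSIM.comment, Literal(ds.comment)))
        if ds.pattern_query:
            graph.add((node, FEDSIM.patternQuery, Literal(ds.pattern_query)))
        for pred in sorted(ds.selected_predicates):
            graph.add((node, FEDSIM.selectedPredicate, URIRef(pred)))

    for topic in registry.topics:
        t_node = FEDSIM[f"Topic_{_slug(topic.name)}"]
        graph.add((t_node, RDF.type, FEDSIM.Topic))
        graph.add((t_node, FEDSIM.topicName, Literal(topic.name)))
        for sub in topic.subtopics:
            s_node = FEDSIM[f"Subtopic_{_slug(sub.name)}"]
            graph.add((t_node, FEDSIM.hasSubTopic, s_node))
            graph.add((s_node, RDF.type, FEDSIM.Subtopic))
            graph.add((s_node, FEDSIM.subtopicName, Literal(sub.name)))
            for tmpl in sub.templates:
                m_node = FEDSIM[f"Template_{tmpl.label}"]
                graph.add((s_node, FEDSIM.hasTemplate, m_node))
                graph.add((m_node, RDF.type, FEDSIM.Template))
                graph.add(
                    (m_node, FEDSIM.templateLabel, Literal(tmpl.label, datatype=XSD.integer))
                )
                graph.add((m_node, FEDSIM.templateName, Literal(tmpl.name)))
                graph.add((m_node, FEDSIM.keywordKind, Literal(tmpl.keyword_kind)))
                graph.add((m_node, FEDSIM.resultVariable, Literal(tmpl.result_variable)))
                graph.add(
                    (m_node, FEDSIM.similarityEnabled, Literal(tmpl.similarity_enabled))
                )
                graph.add(
                    (m_node, FEDSIM.hasInitialQuery,
                     Literal(tmpl.initial_query_pattern.text))
                )
                graph.add(
                    (m_node, FEDSIM.tailReserved,
                     Literal(tmpl.initial_query_pattern.tail_reserved))
                )
                registry_specs = {d.key: d for d in registry.datasets}
                for ds in tmpl.connected_datasets:
                    graph.add((m_node, FEDSIM.connectedWith, ds_nodes[ds.key]))
                    base = registry_specs[ds.key]
                    if ds.pattern_query != base.pattern_query:
                        graph.add(
                            (m_node, FEDSIM.linkPattern,
                             Literal(f"{ds.qualified_name}\n{ds.pattern_query}"))
                        )
                graph.add(
                    (m_node, FEDSIM.datasetOrder,
                     Literal("|".join(ds.qualified_name for ds in tmpl.connected_datasets)))
                )

    text = graph.serialize(format="turtle")
    if destination is not None:
        try:
            Path(destination).write_text(text, encoding="utf-8")
        except OSError as exc:
            raise OSError(f"cannot write registry to {destination}: {exc}") from exc
    return text


def resolve_template(
    registry: Registry, topic: str, subtopic: str, template_label: int
) -> Template:
    """Find the template nested under ``topic``/``subtopic`` with the label.

    Raises :class:`RegistryLookupError` for unknown names/labels and
    :class:`RegistryConsistencyError` when all parts exist but are not
    nested as requested (e.g. the subtopic belongs to another topic).
    """
    all_topics = {t.name: t for t in registry.topics}
    all_subs = {s.name: s for t in registry.topics for s in t.subtopics}
    all_labels = {t.label for t in registry.templates()}
    if topic not in all_topics:
        raise RegistryLookupError(f"unknown topic {topic!r}")
    if subtopic not in all_subs:
        raise RegistryLookupError(f"unknown subtopic {subtopic!r}")
    if template_label not in all_labels:
        raise RegistryLookupError(f"unknown template label {template_label}")
    topic_obj = all_topics[topic]
    sub_obj = next((s for s in topic_obj.subtopics if s.name == subtopic), None)
    if sub_obj is None:
        raise RegistryConsistencyError(
            f"subtopic {subtopic!r} is not under topic {topic!r}"
        )
    tmpl = next((t for t in sub_obj.templates if t.label == template_label), None)
    if tmpl is None:
        raise RegistryConsistencyError(
            f"template {template_label} is not under {topic!r}/{subtopic!r}"
        )
    return tmpl


_REQUIRED_SPEC_FIELDS = ("name", "initiative", "endpoint_url", "pattern_query")


def register_dataset(
    registry: Registry, spec: DatasetSpec, template: Template
) -> Registry:
    """Return a new registry with ``spec`` added and linked to ``template``.

    The input registry is left unmodified.  The spec must be complete and
    its pattern query must bind the template's result variable.
    """
    missing = [f for f in _REQUIRED_SPEC_FIELDS if not getattr(spec, f)]
    if missing:
        raise RegistryValidationError(
            "dataset spec is missing required field(s): " + ", ".join(missing)
        )
    var = f"?{template.result_variable}"
    if var not in spec.pattern_query:
        raise RegistryValidationError(
            f"pattern query must bind {var} (the result variable of template "
            f"{template.label})"
        )
    if any(ds.key == spec.key for ds in registry.datasets):
        raise RegistryValidationError(
            f"dataset {spec.qualified_name} already registered"
        )
    updated = copy.deepcopy(registry)
    updated.datasets.append(spec)
    updated.datasets.sort(key=lambda d: d.key)
    for t in updated.templates():
        if t.label == template.label:
            t.connected_datasets.append(spec)
            return updated
    raise RegistryLookupError(
        f"template {template.label} does not exist in the registry"
    )
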
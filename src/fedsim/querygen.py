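"""Construction of executable SPARQL query texts.

Four query shapes are produced here:

* **federated template queries** — the predefined query of a template, with
  every positional ``%s`` placeholder replaced by the user keyword and the
  reserved tail placeholder replaced by an added dataset's SERVICE block
  (or the empty string);
* **star-shaped filter queries** — one subject variable and k property
  joins, i.e. k+1 triple patterns;
* **profile queries** — all (predicate, object) pairs of one URI;
* **property-list queries** — the distinct predicates used by instances
  matching a template's pattern in one dataset.

Keyword values are always inserted as escaped literal content, never as raw
text, so quote characters cannot break out of the query (placeholders sit
inside double-quoted literals in pattern fragments).  All generated texts
are checked against the SPARQL 1.1 grammar before being returned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence
from urllib.parse import urlparse

from rdflib.plugins.sparql import prepareQuery

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .registry import DatasetSpec, Template

__all__ = [
    "FederatedQuery",
    "QueryGenerationError",
    "QueryPattern",
    "StarQuery",
    "build_profile_query",
    "build_property_list_query",
    "build_star_query",
    "count_triple_patterns",
    "escape_literal",
    "instantiate_query",
]

PLACEHOLDER = "%s"


class QueryGenerationError(ValueError):
    """A generated query failed validation; carries the offending fragment."""


@dataclass(frozen=True)
class QueryPattern:
    """SPARQL text with ordered positional ``%s`` placeholders.

    When ``tail_reserved`` is true the last placeholder is reserved for an
    added dataset's pattern; all earlier placeholders take the keyword.
    """

    text: str
    tail_reserved: bool = True

    @property
    def placeholder_count(self) -> int:
        return self.text.count(PLACEHOLDER)

    def __post_init__(self) -> None:
        if self.tail_reserved and self.placeholder_count < 1:
            raise ValueError(
                "a pattern with a reserved tail needs at least one placeholder"
            )


@dataclass(frozen=True)
class SourceRef:
    """(dataset name, initiative, endpoint URL) of one federated source."""

    name: str
    initiative: str
    endpoint_url: str

    @property
    def qualified_name(self) -> str:
        return f"{self.name}/{self.initiative}"


@dataclass
class FederatedQuery:
    """A complete federated SPARQL query plus its ordered source list.

    ``source_patterns`` holds, aligned with ``sources``, each source's
    graph-pattern fragment with the keyword already substituted; the
    federation layer executes these per source so that every SERVICE
    contributes rows independently (UNION semantics).
    """

    text: str
    sources: list[SourceRef]
    result_variable: str
    source_patterns: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class StarQuery:
    """A star-shaped query: one subject variable, k joins, k+1 triple patterns."""

    text: str
    subject_variable: str
    k: int


def escape_literal(value: str) -> str:
    """Escape a string for inclusion inside a double-quoted SPARQL literal."""
    return (
        value.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
        .replace("\t", "\\t")
    )


def validate_sparql(text: str) -> None:
    """Raise :class:`QueryGenerationError` if ``text`` is not SPARQL 1.1."""
    try:
        prepareQuery(text)
    except Exception as exc:
        raise QueryGenerationError(
            f"generated query does not parse: {exc}\n--- query ---\n{text}"
        ) from exc


def count_triple_patterns(text: str) -> int:
    """Number of triple patterns in a query, via the SPARQL algebra."""
    algebra = prepareQuery(text).algebra

    def walk(node) -> int:
        total = 0
        if hasattr(node, "keys"):
            for key in node:
                if key == "triples":
                    total += len(node[key])
                else:
                    total += walk(node[key])
        elif isinstance(node, (list, tuple)):
            for item in node:
                total += walk(item)
        return total

    return walk(algebra)


def service_block(dataset: "DatasetSpec", keyword: str | None = None) -> str:
    """A ``SERVICE SILENT`` block for one dataset, keyword substituted."""
    pattern = dataset.pattern_query
    if keyword is not None:
        pattern = pattern.replace(PLACEHOLDER, escape_literal(keyword))
    body = "\n".join("      " + line for line in pattern.strip().splitlines())
    return (
        "  { SERVICE SILENT <%s> {\n%s\n  } }" % (dataset.endpoint_url, body)
    )


def assemble_initial_query(
    result_variable: str, datasets: Sequence["DatasetSpec"]
) -> QueryPattern:
    """Build a template's predefined query pattern from its datasets.

    Each dataset contributes one SERVICE block (keyword placeholders kept);
    blocks are combined with UNION so each source contributes rows
    independently.  A final ``%s`` is reserved for an added dataset.
    """
    blocks = [service_block(ds) for ds in datasets]
    body = "\n  UNION\n".join(blocks)
    text = (
        f"SELECT DISTINCT ?{result_variable} WHERE {{\n"
        f"{body}\n"
        f"  {PLACEHOLDER}\n"
        f"}}\n"
    )
    return QueryPattern(text=text, tail_reserved=True)


def instantiate_query(
    template: "Template", keyword: str, added: "DatasetSpec | None" = None
) -> FederatedQuery:
    """Fill a template's placeholders and return the runnable query.

    Every keyword placeholder is replaced by the escaped keyword; the
    reserved tail placeholder becomes the added dataset's SERVICE block
    (with the keyword substituted into its pattern) or the empty string
    when no dataset is added.  No placeholder survives substitution.
    """
    if not keyword or not keyword.strip():
        raise ValueError("keyword must be non-empty")
    pattern = template.initial_query_pattern
    text = pattern.text
    escaped = escape_literal(keyword)

    if added is not None:
        if f"?{template.result_variable}" not in added.pattern_query:
            raise QueryGenerationError(
                f"added dataset pattern must bind ?{template.result_variable}; "
                f"got: {added.pattern_query!r}"
            )
        tail = "UNION\n" + service_block(added, keyword)
    else:
        tail = ""

    if pattern.tail_reserved:
        head, _, rest = text.rpartition(PLACEHOLDER)
        text = head.replace(PLACEHOLDER, escaped) + tail + rest
    else:
        text = text.replace(PLACEHOLDER, escaped)

    if PLACEHOLDER in text:
        raise QueryGenerationError(f"unfilled placeholder remains in:\n{text}")
    validate_sparql(text)

    sources = [
        SourceRef(ds.name, ds.initiative, ds.endpoint_url)
        for ds in template.connected_datasets
    ]
    patterns = [
        ds.pattern_query.replace(PLACEHOLDER, escaped)
        for ds in template.connected_datasets
    ]
    if added is not None:
        sources.append(SourceRef(added.name, added.initiative, added.endpoint_url))
        patterns.append(added.pattern_query.replace(PLACEHOLDER, escaped))
    return FederatedQuery(
        text=text,
        sources=sources,
        result_variable=template.result_variable,
        source_patterns=patterns,
    )


_VAR_RE = re.compile(r"^\?[A-Za-z_][A-Za-z0-9_]*")


def build_star_query(
    dataset: "DatasetSpec",
    subject_variable: str,
    properties: Sequence[str],
    anchor: str,
) -> StarQuery:
    """Build a star-shaped query over ``dataset`` for the given properties.

    ``anchor`` is a single triple pattern whose subject is
    ``subject_variable`` (it ties the star to the running template's
    instances); each of the k properties adds one join with a fresh object
    variable ``?o1..?ok``, all of which are projected.  The result has
    exactly k+1 triple patterns sharing one subject.
    """
    if not properties:
        raise ValueError("select at least one property")
    anchor = anchor.strip().rstrip(".").strip()
    if not anchor.startswith(f"?{subject_variable}"):
        raise QueryGenerationError(
            f"anchor triple must have ?{subject_variable} as subject; got {anchor!r}"
        )
    obj_vars = [f"?o{i}" for i in range(1, len(properties) + 1)]
    joins = "\n".join(
        f"  ?{subject_variable} <{prop}> {var} ."
        for prop, var in zip(properties, obj_vars)
    )
    text = (
        f"SELECT ?{subject_variable} {' '.join(obj_vars)} WHERE {{\n"
        f"  {anchor} .\n"
        f"{joins}\n"
        f"}}\n"
    )
    validate_sparql(text)
    n = count_triple_patterns(text)
    if n != len(properties) + 1:
        raise QueryGenerationError(
            f"star query has {n} triple patterns, expected {len(properties) + 1}:\n{text}"
        )
    return StarQuery(text=text, subject_variable=subject_variable, k=len(properties))


def build_profile_query(uri: str) -> str:
    """Query for the entire (predicate, object) collection of one URI."""
    parsed = urlparse(uri)
    if not parsed.scheme or any(c.isspace() for c in uri) or ">" in uri:
        raise ValueError(f"not an absolute URI: {uri!r}")
    text = f"SELECT ?p ?o WHERE {{ <{uri}> ?p ?o . }}"
    validate_sparql(text)
    return text


def build_property_list_query(dataset: "DatasetSpec", template: "Template") -> str:
    """Query for the distinct predicates of instances matching the template.

    The dataset's pattern fragment is generalised by turning each keyword
    placeholder into a variable, so the query covers all instances matching
    the pattern shape rather than one keyword.
    """
    if dataset.key not in {ds.key for ds in template.connected_datasets}:
        raise ValueError(
            f"dataset {dataset.qualified_name} is not connected to template "
            f"{template.label}"
        )
    pattern = dataset.pattern_query
    i = 0
    while f'"{PLACEHOLDER}"' in pattern:
        pattern = pattern.replace(f'"{PLACEHOLDER}"', f"?kw{i}", 1)
        i += 1
    while PLACEHOLDER in pattern:
        pattern = pattern.replace(PLACEHOLDER, f"?kw{i}", 1)
        i += 1
    body = "\n".join("  " + line for line in pattern.strip().splitlines())
    text = (
        "SELECT DISTINCT ?p WHERE {\n"
        f"{body}\n"
        f"  ?{template.result_variable} ?p ?o .\n"
        "}\n"
    )
    validate_sparql(text)
    return text
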
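"""Execution of federated queries with per-source provenance.

Each source of a federated query is executed independently (UNION
semantics): a reachable source contributes its rows tagged with dataset and
initiative name; an unreachable source contributes zero rows plus a warning
and never an exception — mirroring the SILENT behaviour of federated
SPARQL.  Rows are not deduplicated across sources, since per-source
provenance is the point of the result table.

A :class:`SourceBinding` decides how a source is reached: a local RDF graph
file (Turtle/RDF-XML, queried in process) or a remote SPARQL endpoint over
HTTP (SPARQL Protocol, JSON results).
"""

from __future__ import annotations

import json
import urllib.error
import warnings
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

from rdflib import Graph, Literal, URIRef

from .querygen import FederatedQuery, build_profile_query, validate_sparql
from .similarity import EntityProfile

__all__ = [
    "ResultRow",
    "ResultTable",
    "SourceBinding",
    "SourceUnreachable",
    "execute_federated",
    "fetch_profile",
]

DEFAULT_TIMEOUT = 30.0


class SourceUnreachable(RuntimeError):
    """A source could not be queried (dead endpoint, missing/bad graph file)."""


@dataclass(frozen=True)
class SourceBinding:
    """How one dataset is reached: remote endpoint XOR local graph file."""

    dataset: str
    initiative: str
    endpoint_url: str | None = None
    graph_path: str | None = None

    def __post_init__(self) -> None:
        if bool(self.endpoint_url) == bool(self.graph_path):
            raise ValueError(
                f"binding for {self.dataset}/{self.initiative} must set exactly "
                "one of endpoint_url or graph_path"
            )

    @property
    def qualified_name(self) -> str:
        return f"{self.dataset}/{self.initiative}"


@dataclass(frozen=True)
class ResultRow:
    value: str
    dataset: str
    initiative: str
    is_uri: bool = True


@dataclass
class ResultTable:
    """Rows tagged by source, per-source counts, and source warnings."""

    rows: list[ResultRow] = field(default_factory=list)
    stats: dict[str, int] = field(default_factory=dict)
    warnings: list[tuple[str, str]] = field(default_factory=list)


_GRAPH_CACHE: dict[tuple[str, float], Graph] = {}


def _local_graph(path: str) -> Graph:
    p = Path(path)
    if not p.exists():
        raise SourceUnreachable(f"graph file not found: {path}")
    key = (str(p.resolve()), p.stat().st_mtime)
    if key not in _GRAPH_CACHE:
        g = Graph()
        try:
            g.parse(str(p))
        except Exception as exc:
            raise SourceUnreachable(f"cannot parse graph file {path}: {exc}") from exc
        _GRAPH_CACHE[key] = g
    return _GRAPH_CACHE[key]


def _remote_select(
    endpoint_url: str, query: str, timeout: float
) -> list[dict[str, object]]:
    """SPARQL Protocol SELECT over HTTP, returning term dicts per row."""
    data = urllib.parse.urlencode({"query": query}).encode()
    req = urllib.request.Request(
        endpoint_url,
        data=data,
        headers={
            "Accept": "application/sparql-results+json",
            "Content-Type": "application/x-www-form-urlencoded",
        },
    )
    try:
        with urllib.request.urlopen(req, timeout=timeout) as resp:
            payload = json.load(resp)
    except Exception as exc:  # URLError, timeout, bad JSON, HTTP errors
        raise SourceUnreachable(f"endpoint {endpoint_url} unreachable: {exc}") from exc
    rows = []
    for binding in payload.get("results", {}).get("bindings", []):
        row: dict[str, object] = {}
        for var, term in binding.items():
            if term.get("type") == "uri":
                row[var] = URIRef(term["value"])
            else:
                row[var] = Literal(term["value"])
        rows.append(row)
    return rows


def _run_select(
    binding: SourceBinding, query: str, timeout: float
) -> list[dict[str, object]]:
    if binding.graph_path is not None:
        graph = _local_graph(binding.graph_path)
        result = graph.query(query)
        out = []
        for row in result:
            out.append(dict(zip([str(v) for v in result.vars], row)))
        return out
    return _remote_select(binding.endpoint_url, query, timeout)


def execute_federated(
    query: FederatedQuery,
    bindings: list[SourceBinding],
    timeout: float = DEFAULT_TIMEOUT,
) -> ResultTable:
    """Run each source of ``query`` through its binding and merge the rows.

    Row order is stable: sources in query order, rows in the order the
    source returned them.  A source that is down yields zero rows and one
    warning; when every source is down the result is an empty table with
    warnings, never an exception.  Per-source stats always sum to the total
    row count.
    """
    validate_sparql(query.text)
    by_key = {(b.dataset, b.initiative): b for b in bindings}
    missing = [
        s.qualified_name
        for s in query.sources
        if (s.name, s.initiative) not in by_key
    ]
    if missing:
        raise ValueError("no binding for source(s): " + ", ".join(missing))

    table = ResultTable()
    var = query.result_variable
    for source, pattern in zip(query.sources, query.source_patterns):
        binding = by_key[(source.name, source.initiative)]
        select = f"SELECT ?{var} WHERE {{\n{pattern}\n}}"
        try:
            rows = _run_select(binding, select, timeout)
        except SourceUnreachable as exc:
            table.warnings.append((source.qualified_name, str(exc)))
            table.stats.setdefault(source.qualified_name, 0)
            continue
        count = 0
        for row in rows:
            term = row.get(var)
            if term is None:
                continue
            table.rows.append(
                ResultRow(
                    value=str(term),
                    dataset=source.name,
                    initiative=source.initiative,
                    is_uri=isinstance(term, URIRef),
                )
            )
            count += 1
        table.stats[source.qualified_name] = (
            table.stats.get(source.qualified_name, 0) + count
        )
    return table


def fetch_profile(
    uri: str, binding: SourceBinding, timeout: float = DEFAULT_TIMEOUT
) -> EntityProfile:
    """Fetch all (predicate, object) pairs of ``uri`` at one source.

    Returns an empty profile for a URI unknown to the source; an
    unreachable source also yields an empty profile, with the failure
    recorded for the caller to inspect (raises nothing).
    """
    query = build_profile_query(uri)
    try:
        rows = _run_select(binding, query, timeout)
    except SourceUnreachable as exc:
        warnings.warn(f"profile of {uri} unavailable: {exc}", stacklevel=2)
        return EntityProfile(uri=uri, pairs=[])
    pairs = [(str(row["p"]), row["o"]) for row in rows if "p" in row and "o" in row]
    pairs.sort(key=lambda po: (po[0], str(po[1])))
    return EntityProfile(uri=uri, pairs=pairs)
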
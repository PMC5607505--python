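"""End-to-end orchestration: registry -> query -> execution -> similarity.

Thin glue used by both the command line and programmatic callers; all real
work happens in :mod:`fedsim.registry`, :mod:`fedsim.querygen`,
:mod:`fedsim.federation` and :mod:`fedsim.similarity`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .federation import (
    DEFAULT_TIMEOUT,
    ResultTable,
    SourceBinding,
    execute_federated,
    fetch_profile,
)
from .querygen import FederatedQuery, instantiate_query
from .registry import DatasetSpec, Registry, Template, resolve_template
from .similarity import (
    DEFAULT_THRESHOLD,
    EntityProfile,
    SimilarityRanking,
    StopWordList,
    detect_similar,
    select_object_values,
)

__all__ = ["RunOutcome", "collect_profiles", "run_template", "similar_from_table"]


@dataclass
class RunOutcome:
    """A query run: the instantiated query, its results, and the template."""

    template: Template
    query: FederatedQuery
    table: ResultTable
    added: DatasetSpec | None = None
    notices: list[str] = field(default_factory=list)


def run_template(
    registry: Registry,
    topic: str,
    subtopic: str,
    template_label: int,
    keyword: str,
    bindings: list[SourceBinding],
    added: DatasetSpec | None = None,
    timeout: float = DEFAULT_TIMEOUT,
) -> RunOutcome:
    """Resolve a template, instantiate it with the keyword, and execute it."""
    template = resolve_template(registry, topic, subtopic, template_label)
    query = instantiate_query(template, keyword, added=added)
    table = execute_federated(query, bindings, timeout=timeout)
    return RunOutcome(template=template, query=query, table=table, added=added)


def collect_profiles(
    outcome: RunOutcome,
    bindings: list[SourceBinding],
    mode: str = "selected",
    timeout: float = DEFAULT_TIMEOUT,
) -> tuple[list[EntityProfile], list[str]]:
    """Fetch and predicate-select profiles for the URI rows of a run.

    Only URI-valued rows are eligible (similarity operates on URIs, not on
    literal rows, which are skipped with a notice).  Each profile is
    fetched from the source that contributed the row, and its values are
    selected with that source's selected predicates (or all literal values
    in mode ``"all"``).  Duplicate URIs keep their first occurrence.
    """
    by_key = {(b.dataset, b.initiative): b for b in bindings}
    specs: dict[tuple[str, str], DatasetSpec] = {
        ds.key: ds for ds in outcome.template.connected_datasets
    }
    if outcome.added is not None:
        specs[outcome.added.key] = outcome.added

    notices: list[str] = []
    profiles: list[EntityProfile] = []
    seen: set[str] = set()
    for row in outcome.table.rows:
        if not row.is_uri:
            notices.append(
                f"skipping literal result {row.value!r} from "
                f"{row.dataset}/{row.initiative}: similarity applies to URIs"
            )
            continue
        if row.value in seen:
            continue
        seen.add(row.value)
        binding = by_key.get((row.dataset, row.initiative))
        spec = specs.get((row.dataset, row.initiative))
        if binding is None or spec is None:
            notices.append(
                f"no binding/spec for source {row.dataset}/{row.initiative}; "
                f"skipping {row.value}"
            )
            continue
        profile = fetch_profile(row.value, binding, timeout=timeout)
        profile.selected_values = select_object_values(
            profile, spec.selected_predicates, mode=mode
        )
        profiles.append(profile)
    return profiles, notices


def similar_from_table(
    outcome: RunOutcome,
    bindings: list[SourceBinding],
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "selected",
    stops: StopWordList | None = None,
    weighting: str = "binary",
    timeout: float = DEFAULT_TIMEOUT,
) -> tuple[SimilarityRanking, list[str]]:
    """Detect similar data items among the URI results of a run."""
    if not outcome.template.similarity_enabled:
        raise ValueError(
            f"similar data items detection is disabled for template "
            f"{outcome.template.label} ({outcome.template.name!r})"
        )
    profiles, notices = collect_profiles(
        outcome, bindings, mode=mode, timeout=timeout
    )
    ranking = detect_similar(
        profiles, threshold=threshold, stops=stops, weighting=weighting
    )
    return ranking, notices
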
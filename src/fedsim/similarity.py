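"""Similar-data-item detection over federated query results.

Data items returned by a federated query are URIs that may denote the same
real-world entity (a protein target, an assay, a cell line) under different
identifiers at different endpoints.  Detection works on the *object values*
(strings) attached to each URI under an expert-selected set of predicates:

1. each string is normalised — lowercased, tokenized on ``[a-z0-9]+`` runs,
   stop words removed, tokens Porter-stemmed;
2. the token list becomes a binary term-presence vector in a vector space
   model (VSM);
3. string pairs across two URIs are compared with the cosine similarity
   measure (CSM); for binary vectors this is
   ``|A ∩ B| / (sqrt(|A|) * sqrt(|B|))``;
4. cosines at or above a threshold (default 0.7) are summed per unordered
   URI pair, and URIs are ranked by their total over all qualifying pairs.

Binary presence weighting is the normative mode; a term-frequency mode is
available for comparison (``weighting="tf"``) and produces systematically
different values on repeated terms.
"""

from __future__ import annotations

import itertools
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdflib import Literal, URIRef

from ._porter import stem

__all__ = [
    "DEFAULT_STOP_WORDS",
    "DEFAULT_THRESHOLD",
    "EntityProfile",
    "PairScore",
    "SimilarityRanking",
    "StopWordList",
    "TermVector",
    "cosine",
    "cosine_tf",
    "detect_similar",
    "score_uri_pair",
    "select_object_values",
    "transform_string",
    "vectorize",
]

DEFAULT_THRESHOLD = 0.7

#: Fixed English function-word/pronoun list, applied before stemming.
DEFAULT_STOP_WORDS = frozenset(
    """
    a an and are as at be but by for from had has have he her his if in into
    is it its no nor not of on or our she so such that the their them then
    there these they this to was were what which who whom will with you your
    """.split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class StopWordList:
    """Lowercase tokens removed from strings prior to stemming."""

    words: frozenset[str] = DEFAULT_STOP_WORDS

    @classmethod
    def from_file(cls, path: str) -> "StopWordList":
        with open(path, encoding="utf-8") as fh:
            return cls(frozenset(w.strip().lower() for w in fh if w.strip()))


@dataclass
class EntityProfile:
    """A URI together with its (predicate, object) pairs at one source.

    ``selected_values`` holds the literal object values that survived
    predicate selection and feed the similarity computation.
    """

    uri: str
    pairs: list[tuple[str, object]] = field(default_factory=list)
    selected_values: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TermVector:
    """Binary term-presence vector: a set of stemmed tokens."""

    terms: frozenset[str]

    @property
    def norm(self) -> float:
        return math.sqrt(len(self.terms))

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class PairScore:
    """Aggregated above-threshold cosines between one unordered URI pair."""

    uri_a: str
    uri_b: str
    contributions: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def aggregate(self) -> float:
        return math.fsum(c for _, _, c in self.contributions)


@dataclass
class SimilarityRanking:
    """Ranked URIs plus the pair scores that produced the ranking."""

    ranked_uris: list[str]
    pair_scores: list[PairScore]
    threshold: float = DEFAULT_THRESHOLD


class SelectionError(ValueError):
    """Raised for an unusable predicate-selection configuration."""


def select_object_values(
    profile: EntityProfile,
    selected_predicates: Iterable[str],
    mode: str = "selected",
) -> list[str]:
    """Literal object values of the profile under predicate selection.

    In mode ``"selected"`` only pairs whose predicate is in
    ``selected_predicates`` contribute; in mode ``"all"`` every literal
    object passes (the no-restriction comparison mode).  Order of first
    appearance is kept; duplicates are collapsed.  Non-literal objects
    (URIs, blank nodes) never contribute.
    """
    if mode not in ("selected", "all"):
        raise ValueError(f"unknown mode {mode!r}; expected 'selected' or 'all'")
    wanted = {str(p) for p in selected_predicates}
    if mode == "selected" and not wanted:
        raise SelectionError(
            "predicate selection mode requires at least one selected predicate"
        )
    out: list[str] = []
    seen: set[str] = set()
    for pred, obj in profile.pairs:
        if mode == "selected" and str(pred) not in wanted:
            continue
        if isinstance(obj, URIRef):
            continue
        if isinstance(obj, Literal) and obj.datatype is not None and not isinstance(
            obj.toPython(), str
        ):
            # numeric/typed literals carry no text to compare
            continue
        if not isinstance(obj, (str, Literal)):
            continue
        value = str(obj)
        if value not in seen:
            seen.add(value)
            out.append(value)
    return out


def transform_string(
    s: str, stops: StopWordList | frozenset[str] | None = None
) -> list[str]:
    """Normalise a string to a list of stemmed tokens.

    Lowercases, extracts maximal ``[a-z0-9]+`` runs (every other character,
    including hyphens, parentheses and non-ASCII, acts as a separator),
    drops stop words, then Porter-stems each surviving token.  Stop words
    are checked before stemming so that stemming cannot create or destroy a
    stop-word match.
    """
    if stops is None:
        words = DEFAULT_STOP_WORDS
    elif isinstance(stops, StopWordList):
        words = stops.words
    else:
        words = frozenset(stops)
    tokens = _TOKEN_RE.findall(s.lower())
    return [stem(t) for t in tokens if t not in words]


def vectorize(tokens: Sequence[str]) -> TermVector:
    """Binary presence vector over distinct stemmed tokens."""
    return TermVector(frozenset(tokens))


def cosine(v1: TermVector, v2: TermVector) -> float:
    """Cosine of two binary term vectors; 0 when either is empty.

    Equals the shared-term count divided by the geometric mean of the two
    set sizes, hence lies in [0, 1] and is 1 iff the non-empty sets are
    equal.
    """
    if not v1.terms or not v2.terms:
        return 0.0
    # sqrt of the size product, not a product of sqrts: keeps identical
    # sets at exactly 1.0
    return len(v1.terms & v2.terms) / math.sqrt(len(v1.terms) * len(v2.terms))


def cosine_tf(tokens1: Sequence[str], tokens2: Sequence[str]) -> float:
    """Cosine over raw term-frequency vectors (comparison mode)."""
    c1, c2 = Counter(tokens1), Counter(tokens2)
    if not c1 or not c2:
        return 0.0
    dot = sum(c1[t] * c2[t] for t in c1.keys() & c2.keys())
    n1 = math.sqrt(sum(v * v for v in c1.values()))
    n2 = math.sqrt(sum(v * v for v in c2.values()))
    return dot / (n1 * n2)


def _string_similarity(
    a: str, b: str, stops: StopWordList | None, weighting: str
) -> float:
    ta, tb = transform_string(a, stops), transform_string(b, stops)
    if weighting == "binary":
        return cosine(vectorize(ta), vectorize(tb))
    if weighting == "tf":
        return cosine_tf(ta, tb)
    raise ValueError(f"unknown weighting {weighting!r}; expected 'binary' or 'tf'")


def score_uri_pair(
    a: EntityProfile,
    b: EntityProfile,
    threshold: float = DEFAULT_THRESHOLD,
    stops: StopWordList | None = None,
    weighting: str = "binary",
) -> PairScore:
    """Score one unordered URI pair over the cross-product of their values.

    Every (value of a) x (value of b) string pair is compared; cosines at or
    above ``threshold`` are recorded as contributions and summed into the
    aggregate.  Pairs with no qualifying contribution aggregate to 0.
    """
    score = PairScore(uri_a=a.uri, uri_b=b.uri)
    for sa, sb in itertools.product(a.selected_values, b.selected_values):
        c = _string_similarity(sa, sb, stops, weighting)
        if c >= threshold:
            score.contributions.append((sa, sb, c))
    return score


def detect_similar(
    profiles: Sequence[EntityProfile],
    threshold: float = DEFAULT_THRESHOLD,
    stops: StopWordList | None = None,
    weighting: str = "binary",
) -> SimilarityRanking:
    """Rank URIs by their summed above-threshold pair aggregates.

    All unordered distinct profile pairs are scored; pairs with aggregate 0
    are discarded.  Each URI's rank key is the sum (``math.fsum``, so the
    result is independent of pair enumeration order) of the aggregates of
    every qualifying pair it participates in; ties are broken by input
    order.  URIs in no qualifying pair are excluded from the ranking.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    kept: list[PairScore] = []
    per_uri: dict[str, list[float]] = {}
    for a, b in itertools.combinations(profiles, 2):
        ps = score_uri_pair(a, b, threshold=threshold, stops=stops, weighting=weighting)
        if ps.contributions:
            kept.append(ps)
            per_uri.setdefault(ps.uri_a, []).append(ps.aggregate)
            per_uri.setdefault(ps.uri_b, []).append(ps.aggregate)
    order = {p.uri: i for i, p in enumerate(profiles)}
    ranked = sorted(
        per_uri, key=lambda u: (-math.fsum(per_uri[u]), order.get(u, len(order)))
    )
    return SimilarityRanking(ranked_uris=ranked, pair_scores=kept, threshold=threshold)
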
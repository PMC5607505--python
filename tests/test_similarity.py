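"""String transformation, vector space model, cosine scoring and ranking."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from fedsim.similarity import (
    DEFAULT_STOP_WORDS,
    EntityProfile,
    SelectionError,
    StopWordList,
    cosine,
    cosine_tf,
    detect_similar,
    score_uri_pair,
    select_object_values,
    transform_string,
    vectorize,
)

# Object values of the eight worked-example entities (name/synonym strings
# attached to protein-target URIs at five emulated sources).
VALUES = {
    "URI_1": ["MAPKAP kinase 2", "MAPK-activated protein kinase 2"],
    "URI_2": ["MAP kinase-activated protein kinase 2"],
    "URI_3": ["Dual specificity mitogen-activated protein kinase kinase 1"],
    "URI_4": ["MAP kinase ERK2"],
    "URI_5": ["THP-1"],
    "URI_6": ["MAPK-Activated Protein Kinase 2 (MK2)"],
    "URI_7": ["MAPKAPK-2", "MAPK-activated protein kinase 2"],
    "URI_8": ["Histidine-containing protein", "Phosphocarrier protein HPr"],
}


def make_profiles():
    return [
        EntityProfile(uri=name, selected_values=list(vals))
        for name, vals in VALUES.items()
    ]


class TestTransformString:
    @pytest.mark.parametrize(
        "text, expected",
        [
            (
                "MAPK-Activated Protein Kinase 2 (MK2)",
                ["mapk", "activ", "protein", "kinas", "2", "mk2"],
            ),
            ("of the and", []),
            ("", []),
            ("THP-1", ["thp", "1"]),
            ("them who that", []),
        ],
    )
    def test_examples(self, text, expected):
        assert transform_string(text) == expected

    def test_non_ascii_characters_separate_tokens(self):
        assert transform_string("β-catenin protein") == ["catenin", "protein"]

    def test_stop_words_checked_before_stemming(self):
        # 'beings' stems to 'be', which is a stop word; removal happens
        # before stemming, so the stemmed token survives
        assert "be" in DEFAULT_STOP_WORDS
        assert transform_string("beings") == ["be"]

    def test_custom_stop_word_list(self):
        stops = StopWordList(frozenset({"protein"}))
        assert transform_string("protein kinase", stops) == ["kinas"]


class TestVectorize:
    def test_collapses_duplicates(self):
        v = vectorize(["map", "kinas", "activ", "protein", "kinas", "2"])
        assert v.terms == {"map", "kinas", "activ", "protein", "2"}
        assert len(v) == 5

    def test_empty(self):
        assert len(vectorize([])) == 0

    def test_idempotent_on_set_listing(self):
        v = vectorize(["a1", "b2"])
        assert vectorize(sorted(v.terms)).terms == v.terms


class TestCosine:
    def test_identical_nonempty_is_one(self):
        v = vectorize(["kinas", "2"])
        assert cosine(v, v) == 1.0

    def test_disjoint_is_zero(self):
        assert cosine(vectorize(["x1"]), vectorize(["y2"])) == 0.0

    def test_half_overlap(self):
        assert cosine(vectorize(["a1", "b1"]), vectorize(["a1", "c1"])) == 0.5

    def test_empty_vector_gives_zero(self):
        assert cosine(vectorize([]), vectorize(["a1"])) == 0.0

    def test_worked_example_value(self):
        v1 = vectorize(transform_string("MAPK-activated protein kinase 2"))
        v2 = vectorize(transform_string("MAPK-Activated Protein Kinase 2 (MK2)"))
        assert cosine(v1, v2) == pytest.approx(0.912871, abs=1e-6)


token = st.text(alphabet="abcdefgh12", min_size=1, max_size=4)
token_sets = st.frozensets(token, max_size=8)


@settings(derandomize=True, max_examples=200)
@given(token_sets, token_sets)
def test_cosine_symmetry_and_bounds(a, b):
    va, vb = vectorize(sorted(a)), vectorize(sorted(b))
    c = cosine(va, vb)
    assert c == cosine(vb, va)
    assert 0.0 <= c <= 1.0
    if a and b:
        assert (c == 1.0) == (a == b)


@settings(derandomize=True, max_examples=200)
@given(token_sets, token_sets)
def test_cosine_matches_explicit_binary_vector_oracle(a, b):
    """Set formula == dot product over an explicit vocabulary-indexed 0/1 vector."""
    vocab = sorted(a | b)
    xa = [1 if t in a else 0 for t in vocab]
    xb = [1 if t in b else 0 for t in vocab]
    dot = sum(x * y for x, y in zip(xa, xb))
    na, nb = math.sqrt(sum(xa)), math.sqrt(sum(xb))
    expected = dot / (na * nb) if na and nb else 0.0
    assert cosine(vectorize(sorted(a)), vectorize(sorted(b))) == pytest.approx(expected)


class TestSelectObjectValues:
    def test_selected_predicates_filter(self):
        profile = EntityProfile(
            uri="u",
            pairs=[
                ("http://example.org/p1", "keep me"),
                ("http://example.org/p2", "drop me"),
                ("http://example.org/p1", "keep me"),  # duplicate collapsed
            ],
        )
        assert select_object_values(profile, {"http://example.org/p1"}) == ["keep me"]

    def test_disjoint_predicates_give_empty(self):
        profile = EntityProfile(uri="u", pairs=[("http://example.org/p", "v")])
        assert select_object_values(profile, {"http://example.org/other"}) == []

    def test_all_mode_passes_every_literal(self):
        profile = EntityProfile(
            uri="u",
            pairs=[("http://example.org/p1", "a"), ("http://example.org/p2", "b")],
        )
        assert select_object_values(profile, set(), mode="all") == ["a", "b"]

    def test_empty_selection_in_selected_mode_is_an_error(self):
        profile = EntityProfile(uri="u", pairs=[])
        with pytest.raises(SelectionError):
            select_object_values(profile, set(), mode="selected")


class TestScoreUriPair:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("URI_1", "URI_2", 0.8),
            ("URI_1", "URI_6", 0.912871),
            ("URI_1", "URI_7", 1.0),
            ("URI_2", "URI_6", 0.730297),
            ("URI_2", "URI_7", 0.8),
            ("URI_6", "URI_7", 0.912871),
        ],
    )
    def test_worked_example_aggregates(self, a, b, expected):
        pa = EntityProfile(uri=a, selected_values=VALUES[a])
        pb = EntityProfile(uri=b, selected_values=VALUES[b])
        assert score_uri_pair(pa, pb).aggregate == pytest.approx(expected, abs=1e-6)

    def test_no_qualifying_pair_aggregates_to_zero(self):
        pa = EntityProfile(uri="URI_1", selected_values=VALUES["URI_1"])
        pb = EntityProfile(uri="URI_8", selected_values=VALUES["URI_8"])
        score = score_uri_pair(pa, pb)
        assert score.contributions == []
        assert score.aggregate == 0.0

    def test_every_contribution_meets_threshold(self):
        pa = EntityProfile(uri="URI_1", selected_values=VALUES["URI_1"])
        pb = EntityProfile(uri="URI_7", selected_values=VALUES["URI_7"])
        score = score_uri_pair(pa, pb, threshold=0.7)
        assert all(c >= 0.7 for _, _, c in score.contributions)
        # only one of the four cross-product string pairs qualifies
        assert len(score.contributions) == 1


def test_term_frequency_weighting_disagrees_with_binary():
    """With raw term frequencies the repeated 'kinase' shifts the score
    from 0.8 to 5/sqrt(40) ~ 0.7906, so binary presence weighting is the
    mode that matches the reference values."""
    t1 = transform_string("MAPK-activated protein kinase 2")
    t2 = transform_string("MAP kinase-activated protein kinase 2")
    tf = cosine_tf(t1, t2)
    assert tf == pytest.approx(5 / math.sqrt(40), abs=1e-9)
    assert abs(tf - 0.8) > 0.005
    assert cosine(vectorize(t1), vectorize(t2)) == pytest.approx(0.8, abs=1e-9)


class TestDetectSimilar:
    def test_worked_example_ranking(self):
        ranking = detect_similar(make_profiles())
        assert ranking.ranked_uris == ["URI_1", "URI_7", "URI_6", "URI_2"]
        assert len(ranking.pair_scores) == 6

    def test_per_uri_aggregate_sums(self):
        ranking = detect_similar(make_profiles())
        sums = {}
        for ps in ranking.pair_scores:
            sums[ps.uri_a] = sums.get(ps.uri_a, 0.0) + ps.aggregate
            sums[ps.uri_b] = sums.get(ps.uri_b, 0.0) + ps.aggregate
        assert sums["URI_1"] == pytest.approx(2.712871, abs=1e-6)
        assert sums["URI_7"] == pytest.approx(2.712871, abs=1e-6)
        assert sums["URI_6"] == pytest.approx(2.556039, abs=1e-6)
        assert sums["URI_2"] == pytest.approx(2.330297, abs=1e-6)

    def test_single_profile_gives_empty_ranking(self):
        ranking = detect_similar([EntityProfile(uri="u", selected_values=["x"])])
        assert ranking.ranked_uris == []
        assert ranking.pair_scores == []

    def test_identical_strings_rank_in_input_order(self):
        p1 = EntityProfile(uri="first", selected_values=["same name"])
        p2 = EntityProfile(uri="second", selected_values=["same name"])
        ranking = detect_similar([p1, p2])
        assert ranking.ranked_uris == ["first", "second"]
        assert ranking.pair_scores[0].aggregate == pytest.approx(1.0)

    def test_threshold_one_keeps_only_exact_duplicates(self):
        ranking = detect_similar(make_profiles(), threshold=1.0)
        assert ranking.ranked_uris == ["URI_1", "URI_7"]

    def test_threshold_monotonicity(self):
        base = detect_similar(make_profiles(), threshold=0.7)
        for thr in (0.75, 0.85, 0.95):
            higher = detect_similar(make_profiles(), threshold=thr)
            assert set(higher.ranked_uris) <= set(base.ranked_uris)
            n_base = sum(len(p.contributions) for p in base.pair_scores)
            n_high = sum(len(p.contributions) for p in higher.pair_scores)
            assert n_high <= n_base

    def test_ranking_content_invariant_under_permutation(self):
        profiles = make_profiles()
        forward = detect_similar(profiles)
        backward = detect_similar(list(reversed(profiles)))
        assert set(forward.ranked_uris) == set(backward.ranked_uris)
        agg = lambda r: sorted(
            (tuple(sorted((p.uri_a, p.uri_b))), round(p.aggregate, 12))
            for p in r.pair_scores
        )
        assert agg(forward) == agg(backward)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_similar(make_profiles(), threshold=0.0)
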
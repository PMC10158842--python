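"""Fuzzy matcher: distance/ratio primitives against independent oracles,
sliding-window semantics, lexicon refinement, review sampling."""

import math
import random
from functools import lru_cache

import edlib
import pytest
from hypothesis import given, strategies as st

from barrier_miner.match import (
    Lexicon,
    LexiconError,
    MatcherConfig,
    SearchExpression,
    _bounded_distance,
    edit_distance,
    expand_alternations,
    find_matches,
    levenshtein_ratio,
    load_lexicon,
    refine_lexicon,
    sample_for_review,
    save_lexicon,
    scan_corpus,
)
from barrier_miner.normalize import NormalizedPost, normalize_post
from .conftest import make_post


def oracle_distance(a: str, b: str, sub_cost: int) -> int:
    """Independent top-down DP oracle (recursion + memo)."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (0 if a[i - 1] == b[j - 1] else sub_cost),
        )

    return d(len(a), len(b))


def indel_oracle(a: str, b: str) -> int:
    """Minimal cost using insertions/deletions only (no substitutions)."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        best = min(d(i - 1, j) + 1, d(i, j - 1) + 1)
        if a[i - 1] == b[j - 1]:
            best = min(best, d(i - 1, j - 1))
        return best

    return d(len(a), len(b))


def np_from_tokens(tokens, post_id="p"):
    offsets = []
    pos = 0
    for t in tokens:
        offsets.append((pos, pos + len(t)))
        pos += len(t) + 1
    return NormalizedPost(post_id=post_id, tokens=tuple(tokens), token_offsets=tuple(offsets))


short_abc = st.text(alphabet="abc", max_size=12)


class TestEditDistance:
    @pytest.mark.parametrize(
        ("a", "b", "cost", "expected"),
        [
            ("abc", "abc", 1, 0),
            ("abc", "abc", 2, 0),
            ("", "abc", 1, 3),
            ("kitten", "sitting", 1, 3),      # frozen from the DP oracle
            ("insurance", "insurence", 2, 2),  # one substitution at cost 2
            ("ab", "cd", 2, 4),
        ],
    )
    def test_frozen_oracle_values(self, a, b, cost, expected):
        assert oracle_distance(a, b, cost) == expected  # oracle agrees first
        assert edit_distance(a, b, cost) == expected

    @given(short_abc, short_abc, st.sampled_from([1, 2]))
    def test_matches_recursive_oracle(self, a, b, cost):
        assert edit_distance(a, b, cost) == oracle_distance(a, b, cost)

    @given(short_abc, short_abc)
    def test_unit_cost_matches_edlib(self, a, b):
        if a and b:  # edlib requires non-empty inputs
            expected = edlib.align(a, b)["editDistance"]
            assert edit_distance(a, b, 1) == expected

    @given(short_abc, short_abc, st.sampled_from([1, 2]))
    def test_symmetry_and_identity(self, a, b, cost):
        assert edit_distance(a, b, cost) == edit_distance(b, a, cost)
        assert (edit_distance(a, b, cost) == 0) == (a == b)

    @given(short_abc, short_abc, short_abc)
    def test_triangle_inequality_unit_cost(self, a, b, c):
        assert edit_distance(a, c, 1) <= edit_distance(a, b, 1) + edit_distance(b, c, 1)

    @given(short_abc, short_abc)
    def test_cost2_reduces_to_indel_only(self, a, b):
        """At substitution cost 2 a substitution is never beneficial."""
        assert edit_distance(a, b, 2) == indel_oracle(a, b)

    @given(short_abc, short_abc, st.integers(0, 6), st.sampled_from([1, 2]))
    def test_bounded_variant_agrees_with_full(self, a, b, limit, cost):
        full = edit_distance(a, b, cost)
        bounded = _bounded_distance(a, b, limit, cost)
        assert bounded == (full if full <= limit else None)

    def test_invalid_substitution_cost(self):
        with pytest.raises(ValueError):
            edit_distance("a", "b", 3)


class TestLevenshteinRatio:
    def test_identity_and_empty(self):
        assert levenshtein_ratio("abc", "abc") == 1.0
        assert levenshtein_ratio("", "") == 1.0

    def test_misspelled_insurance_fails_threshold(self):
        ratio = levenshtein_ratio("insurance", "insurence")
        assert ratio == pytest.approx(16 / 18)
        assert not ratio > 0.9

    def test_pluralized_wait_time_passes_threshold(self):
        ratio = levenshtein_ratio("wait time", "wait times")
        assert ratio == pytest.approx(18 / 19)
        assert ratio > 0.9

    @given(short_abc, short_abc)
    def test_bounds_and_symmetry(self, a, b):
        r = levenshtein_ratio(a, b)
        assert 0.0 <= r <= 1.0
        assert r == levenshtein_ratio(b, a)
        assert (r == 1.0) == (a == b)


class TestFindMatches:
    def test_exact_token_hit(self):
        np_ = np_from_tokens(["my", "insurance", "denied", "it"])
        expr = SearchExpression("insurance", "insurance")
        (m,) = find_matches(np_, expr)
        assert m.token_span == (1, 2) and m.ratio == 1.0
        assert m.window_text == "insurance"

    def test_single_substitution_misspelling_rejected(self):
        np_ = np_from_tokens(["my", "insurence", "denied", "it"])
        assert find_matches(np_, SearchExpression("insurance", "insurance")) == []

    def test_two_word_window_with_plural(self):
        np_ = np_from_tokens(["the", "wait", "times", "were", "long"])
        (m,) = find_matches(np_, SearchExpression("wait time", "logistics"))
        assert m.token_span == (1, 3)
        assert m.ratio == pytest.approx(18 / 19)

    @pytest.mark.parametrize("n_tokens,width", [(0, 1), (3, 1), (3, 2), (3, 3), (2, 3), (10, 4)])
    def test_window_count(self, n_tokens, width):
        np_ = np_from_tokens([f"tok{i}" for i in range(n_tokens)])
        expr = SearchExpression(" ".join(["word"] * width), "other")
        counter: list[int] = []
        find_matches(np_, expr, window_counter=counter)
        assert sum(counter) == max(0, n_tokens - width + 1)

    def test_overlapping_windows_each_match(self):
        np_ = np_from_tokens(["stigma", "stigma", "stigma"])
        matches = find_matches(np_, SearchExpression("stigma", "stigma"))
        assert [m.token_span for m in matches] == [(0, 1), (1, 2), (2, 3)]

    def test_threshold_monotonicity(self, seed_lexicon):
        rng = random.Random(99)
        vocab = ["insurance", "insurence", "stigma", "wait", "time", "times",
                 "clinic", "clinics", "junkie", "junky", "the", "my", "long"]
        posts = [
            np_from_tokens([rng.choice(vocab) for _ in range(rng.randint(1, 15))], f"p{i}")
            for i in range(60)
        ]
        previous: set[str] = set()
        for thr in (0.95, 0.9, 0.8, 0.5):
            _, retrieved = scan_corpus(posts, seed_lexicon, MatcherConfig(threshold=thr))
            assert previous <= retrieved
            previous = retrieved

    def test_substitution_cost_one_flips_outcome(self):
        """One substitution in a 9-letter word: 0.889 at cost 2, 0.944 at cost 1."""
        np_ = np_from_tokens(["insurence"])
        expr = SearchExpression("insurance", "insurance")
        assert find_matches(np_, expr, MatcherConfig(substitution_cost=2)) == []
        (m,) = find_matches(np_, expr, MatcherConfig(substitution_cost=1))
        assert m.ratio == pytest.approx(17 / 18)


class TestScanCorpus:
    def test_single_exact_hit_retrieves_post(self):
        lex = Lexicon(expressions=(SearchExpression("stigma", "stigma"),))
        np_ = np_from_tokens(["stigma", "sucks"], "p9")
        matches, retrieved = scan_corpus([np_], lex)
        assert retrieved == {"p9"} and len(matches) == 1

    def test_empty_lexicon(self):
        np_ = np_from_tokens(["anything"], "p1")
        matches, retrieved = scan_corpus([np_], Lexicon(expressions=()))
        assert matches == [] and retrieved == set()

    def test_quoted_insurance_post_retrieved(self, seed_lexicon, example_posts):
        """A real denied-script post is retrieved via the 'insurance' expression."""
        post = next(p for p in example_posts if "denying my script" in p.text)
        matches, retrieved = scan_corpus([normalize_post(post)], seed_lexicon)
        assert post.post_id in retrieved
        assert any(m.expression_surface == "insurance" for m in matches)

    def test_post_counted_once_despite_many_matches(self, seed_lexicon):
        np_ = np_from_tokens(["insurance", "stigma", "insurance"], "p1")
        matches, retrieved = scan_corpus([np_], seed_lexicon)
        assert len(matches) >= 3 and retrieved == {"p1"}


class TestLexicon:
    def test_alternation_expansion(self):
        assert expand_alternations("drug [ab]user") == ["drug user", "drug abuser"]
        assert expand_alternations("plain") == ["plain"]

    def test_seed_lexicon_contents(self, seed_lexicon):
        assert "drug user" in seed_lexicon.surfaces()
        assert "drug abuser" in seed_lexicon.surfaces()
        assert seed_lexicon.theme_of("childcare") == "logistics"

    def test_refine_add_and_version(self, seed_lexicon):
        v2 = refine_lexicon(seed_lexicon, add=[("prior auth", "insurance")], note="review 1")
        assert "prior auth" in v2.surfaces()
        assert v2.version == seed_lexicon.version + 1
        assert v2.changelog[-1].note == "review 1"

    def test_remove_then_readd_reconstructable(self, seed_lexicon):
        v2 = refine_lexicon(seed_lexicon, remove=["near"], note="too noisy")
        v3 = refine_lexicon(v2, add=[("near", "facility_location")], note="back in")
        assert v3.surfaces() == seed_lexicon.surfaces()
        assert len(v3.changelog) == len(seed_lexicon.changelog) + 2
        assert v3.surfaces_at_version(v2.version) == v2.surfaces()
        assert v3.surfaces_at_version(seed_lexicon.version) == seed_lexicon.surfaces()

    def test_duplicate_add_and_absent_remove_rejected(self, seed_lexicon):
        with pytest.raises(LexiconError):
            refine_lexicon(seed_lexicon, add=[("stigma", "stigma")])
        with pytest.raises(LexiconError):
            refine_lexicon(seed_lexicon, remove=["not there"])

    def test_yaml_round_trip(self, seed_lexicon, tmp_path):
        path = tmp_path / "lex.yaml"
        save_lexicon(seed_lexicon, path)
        again = load_lexicon(path)
        assert again.surfaces() == seed_lexicon.surfaces()
        assert again.version == seed_lexicon.version

    def test_duplicate_surface_rejected(self):
        e = SearchExpression("stigma", "stigma")
        with pytest.raises(LexiconError):
            Lexicon(expressions=(e, e))


class TestSampleForReview:
    def _matches(self, n):
        np_ = np_from_tokens(["stigma"] * n)
        return find_matches(np_, SearchExpression("stigma", "stigma"))

    def test_k_at_least_n_returns_all(self):
        matches = self._matches(5)
        assert sample_for_review(matches, 10, seed=1) == matches

    def test_same_seed_same_sample(self):
        matches = self._matches(50)
        assert sample_for_review(matches, 10, 7) == sample_for_review(matches, 10, 7)

    def test_uniform_inclusion_frequency(self):
        """k of n sampling: every record's inclusion rate is close to k/n.

        Each record's frequency over many seeds is binomial(reps, k/n); the
        mean absolute deviation stays within 3 SEs, and no single record may
        stray beyond a multiplicity-adjusted 4.5-SE band (100 simultaneous
        binomial checks)."""
        matches = self._matches(100)
        k, reps = 10, 2000
        counts = [0] * 100
        for seed in range(reps):
            for m in sample_for_review(matches, k, seed):
                counts[m.token_span[0]] += 1
        p = k / 100
        se = math.sqrt(p * (1 - p) / reps)
        devs = [abs(c / reps - p) for c in counts]
        assert sum(devs) / len(devs) <= 3 * se
        assert max(devs) <= 4.5 * se

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            sample_for_review([], 0, seed=1)
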
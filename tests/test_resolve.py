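"""Two-stage lexical resolution: exact match, then weighted partial match."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import chemner as cn
from chemner.lexicon import LexiconTerm, descriptor_words
from chemner.resolve import SYNONYM_WEIGHT


@pytest.fixture
def index(toy_lexicon):
    return cn.build_index(toy_lexicon)


def brute_force_partial(surface, terms, index):
    """Independent scorer: enumerate every (term, descriptor) pair directly
    from the term list, keep each term's best descriptor, rank."""
    query = descriptor_words(surface)
    rows = []
    for term in terms:
        best = None
        for k, desc in enumerate(term.descriptors):
            words = descriptor_words(desc)
            shared = query & words
            if not shared:
                continue
            denom = sum(index.ec[w] for w in words if w in index.ec)
            numer = sum(index.ec[w] for w in shared if w in index.ec)
            if denom == 0 or numer == 0:
                continue
            weight = 1.0 if k == 0 else SYNONYM_WEIGHT
            cand = (-weight * numer / denom, k != 0, -numer, len(words),
                    term.term_id)
            if best is None or cand < best:
                best = cand
        if best is not None:
            rows.append(best)
    rows.sort()
    return [(row[-1], -row[0]) for row in rows]


class TestExact:
    def test_name_match_scores_one(self, index):
        res = cn.resolve_exact("water", index)
        assert (res.term_id, res.score, res.match_kind) == (
            "CHEBI:15377", 1.0, "name-exact",
        )

    def test_synonym_match_scores_point_eight(self, index):
        res = cn.resolve_exact("aqua", index)
        assert (res.term_id, res.score) == ("CHEBI:15377", 0.8)
        assert res.match_kind == "synonym-exact"

    def test_case_folded(self, index):
        assert cn.resolve_exact("Ethyl Alcohol", index).term_id == "CHEBI:16236"

    def test_unknown_surface_absent(self, index):
        assert cn.resolve_exact("xyzzy", index) is None

    def test_containment_is_not_exact_match(self, index):
        # a surface *containing* a descriptor is partial-match territory
        assert cn.resolve_exact("dimethyl sulphate", index) is None


class TestPartial:
    def test_full_synonym_coverage_scores_point_eight(self):
        terms = [
            LexiconTerm("X:1", "hyaluronan", ("hyaluronic acid",)),
            LexiconTerm("X:2", "glucose", ()),
            LexiconTerm("X:3", "benzene", ()),
        ]
        index = cn.build_index(terms)
        results = cn.resolve_partial("acid hyaluronic", index)
        assert results[0].term_id == "X:1"
        assert results[0].score == pytest.approx(0.8, abs=1e-12)
        assert results[0].match_kind == "partial-synonym"

    def test_superset_of_name_scores_one(self, index):
        results = cn.resolve_partial("zinc oxide nanoparticles", index)
        assert results[0].term_id == "CHEBI:30563"
        assert results[0].score == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_toy_scores(self):
        terms = [
            LexiconTerm("X:1", "hyaluronic acid", ()),
            LexiconTerm("X:2", "acetic acid", ("vinegar acid",)),
            LexiconTerm("X:3", "sodium salt", ()),
            LexiconTerm("X:4", "hyaluronate", ()),
            LexiconTerm("X:5", "benzene", ()),
        ]
        index = cn.build_index(terms)
        n = 5
        ec_acid = -math.log(2 / n)      # in X:1 and X:2
        ec_hyal = -math.log(1 / n)      # "hyaluronic" only in X:1
        ec_salt = -math.log(1 / n)
        ec_sodium = -math.log(1 / n)
        results = cn.resolve_partial("hyaluronic acid salt", index)
        by_id = {r.term_id: r for r in results}
        ec_acetic = -math.log(1 / n)
        assert by_id["X:1"].score == pytest.approx(1.0, abs=1e-12)
        assert by_id["X:2"].score == pytest.approx(
            ec_acid / (ec_acetic + ec_acid), abs=1e-12
        )
        assert by_id["X:3"].score == pytest.approx(
            ec_salt / (ec_sodium + ec_salt), abs=1e-12
        )
        assert ec_hyal == pytest.approx(math.log(n))
        assert "X:4" not in by_id and "X:5" not in by_id
        oracle = brute_force_partial("hyaluronic acid salt", terms, index)
        assert [r.term_id for r in results] == [tid for tid, _ in oracle]
        assert [r.score for r in results] == pytest.approx([s for _, s in oracle])

    def test_empty_word_set_warns_and_returns_nothing(self, index):
        with pytest.warns(UserWarning):
            assert cn.resolve_partial("of the", index) == []

    def test_scores_bounded_by_desc(self, index):
        for surface in ("zinc compounds", "ethyl things", "hydrogen acid",
                        "methyl alcohol mixture"):
            for r in cn.resolve_partial(surface, index):
                desc = 1.0 if r.match_kind == "partial-name" else 0.8
                assert 0.0 < r.score <= desc + 1e-12

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_ranking_matches_brute_force_on_random_queries(self, seed):
        import numpy as np

        lexicon = cn.make_lexicon(cn.FixtureConfig(seed=29, n_terms=60))
        index = cn.build_index(lexicon)
        rng = np.random.default_rng(seed)
        vocab = sorted(index.ec)
        words = [vocab[i] for i in rng.integers(0, len(vocab), rng.integers(1, 4))]
        if rng.random() < 0.5:
            words.append("unrelatedword")
        surface = " ".join(words)
        got = cn.resolve_partial(surface, index)
        oracle = brute_force_partial(surface, lexicon, index)
        assert [r.term_id for r in got] == [tid for tid, _ in oracle]
        assert [r.score for r in got] == pytest.approx([s for _, s in oracle])


class TestTwoStage:
    def test_exact_match_short_circuits(self, index):
        res = cn.resolve("water", index)
        assert res.match_kind == "name-exact" and res.score == 1.0

    def test_falls_back_to_partial(self, index):
        res = cn.resolve("zinc oxide nanoparticles", index)
        assert res.term_id == "CHEBI:30563"
        assert res.score == pytest.approx(1.0)
        assert res.match_kind == "partial-name"

    def test_empty_surface_absent(self, index):
        assert cn.resolve("", index) is None

    def test_no_shared_words_absent(self, index):
        assert cn.resolve("qwerty asdf", index) is None


class TestScoreInvariances:
    def test_log_base_invariance(self, toy_lexicon):
        e_index = cn.build_index(toy_lexicon)
        b2_index = cn.build_index(toy_lexicon, log_base=2.0)
        for surface in ("zinc oxide nanoparticles", "ethyl mixture",
                        "hydrogen rich water"):
            a = cn.resolve_partial(surface, e_index)
            b = cn.resolve_partial(surface, b2_index)
            assert [r.term_id for r in a] == [r.term_id for r in b]
            assert [r.score for r in a] == pytest.approx(
                [r.score for r in b], abs=1e-12
            )

    def test_duplicate_synonym_changes_no_score(self):
        base = [
            LexiconTerm("X:1", "zinc oxide", ("zinc white",)),
            LexiconTerm("X:2", "zinc chloride", ()),
            LexiconTerm("X:3", "water", ()),
        ]
        duped = [
            LexiconTerm("X:1", "zinc oxide", ("zinc white", "zinc white")),
            base[1], base[2],
        ]
        ia, ib = cn.build_index(base), cn.build_index(duped)
        for surface in ("zinc", "white zinc powder", "zinc oxide layer"):
            a = [(r.term_id, r.score) for r in cn.resolve_partial(surface, ia)]
            b = [(r.term_id, r.score) for r in cn.resolve_partial(surface, ib)]
            assert a == b

    def test_adding_shared_word_never_decreases_score(self, index):
        before = {r.term_id: r.score for r in cn.resolve_partial("zinc", index)}
        after = {r.term_id: r.score for r in cn.resolve_partial("zinc oxide", index)}
        for term_id, score in before.items():
            assert after.get(term_id, 0.0) >= score - 1e-12
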
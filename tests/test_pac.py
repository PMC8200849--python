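"""Phone-attribute codebook classifier: quantization, matching, voting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pdvoice import pac
from pdvoice.errors import ConfigurationError, DegenerateCodebookError, UndecidableError
from pdvoice.features import PosteriorStream
from pdvoice.synthetic import ATTRIBUTES


def bits(*idx):
    v = np.zeros(21, dtype=np.uint8)
    v[list(idx)] = 1
    return v


code_arrays = st.lists(
    st.lists(st.integers(0, 1), min_size=21, max_size=21), min_size=1, max_size=50
).map(lambda rows: np.array(rows, dtype=np.uint8))


class TestQuantize:
    def test_threshold_rule(self):
        row = np.zeros((1, 21))
        row[0, :3] = [0.9, 0.3, 0.7]
        assert list(pac.quantize(row)[0, :3]) == [1, 0, 1]

    def test_all_zero_frame(self):
        assert pac.quantize(np.zeros((1, 21))).sum() == 0

    def test_boundary_half_maps_to_one(self):
        row = np.full((1, 21), 0.5)
        assert pac.quantize(row).sum() == 21

    def test_one_code_per_frame(self):
        stream = PosteriorStream(np.random.default_rng(0).random((30, 21)), ATTRIBUTES)
        assert pac.quantize(stream).shape == (30, 21)


class TestCodebooks:
    def test_dedup_with_counts(self):
        a, b = bits(0, 1), bits(2)
        stream = PosteriorStream(np.array([a, a, b], dtype=float), ATTRIBUTES)
        on, off = pac.build_codebooks({"ON": [stream], "OFF": [stream]}, "pataka")
        assert len(on) == 2
        assert on.codes[int(pac.pack_codes(a[None])[0])] == 2
        assert on.codes[int(pac.pack_codes(b[None])[0])] == 1

    def test_empty_class_rejected(self):
        stream = PosteriorStream(np.zeros((2, 21)), ATTRIBUTES)
        with pytest.raises(ConfigurationError, match="OFF"):
            pac.build_codebooks({"ON": [stream]}, "vowels")

    def test_make_unique_removes_shared(self):
        on = pac.Codebook({1: 1, 2: 1, 3: 1}, "ON", "pataka")
        off = pac.Codebook({2: 2, 5: 1}, "OFF", "pataka")
        pair = pac.make_unique(on, off)
        assert pair.on_codes.code_set == {1, 3}
        assert pair.off_codes.code_set == {5}

    def test_identical_codebooks_degenerate(self):
        on = pac.Codebook({1: 1, 2: 1}, "ON", "pataka")
        off = pac.Codebook({1: 3, 2: 1}, "OFF", "pataka")
        with pytest.raises(DegenerateCodebookError):
            pac.make_unique(on, off)

    def test_disjoint_codebooks_unchanged(self):
        on = pac.Codebook({1: 1}, "ON", "pataka")
        off = pac.Codebook({2: 1}, "OFF", "pataka")
        pair = pac.make_unique(on, off)
        assert pair.on_codes.code_set == {1} and pair.off_codes.code_set == {2}

    def test_cross_protocol_pairing_rejected(self):
        with pytest.raises(ConfigurationError):
            pac.make_unique(
                pac.Codebook({1: 1}, "ON", "pataka"), pac.Codebook({2: 1}, "OFF", "vowels")
            )

    def test_json_roundtrip(self):
        pair = pac.make_unique(
            pac.Codebook({7: 2, 9: 1}, "ON", "digits"), pac.Codebook({12: 4}, "OFF", "digits")
        )
        back = pac.codebook_from_json(pac.codebook_to_json(pair))
        assert back.on_codes.codes == pair.on_codes.codes
        assert back.off_codes.codes == pair.off_codes.codes
        assert back.on_codes.protocol == "digits"


def jaccard_oracle(a, b):
    """Literal count of the three match types over the two bit vectors."""
    n11 = sum(1 for x, y in zip(a, b) if x == 1 and y == 1)
    n10 = sum(1 for x, y in zip(a, b) if x == 1 and y == 0)
    n01 = sum(1 for x, y in zip(a, b) if x == 0 and y == 1)
    if n11 + n10 + n01 == 0:
        return 1.0
    return n11 / (n11 + n10 + n01)


class TestJaccard:
    def test_enumerated_example_one_third(self):
        a = bits(0, 1)  # (1,1,0,0,...)
        b = bits(0, 2)  # (1,0,1,0,...)
        assert pac.jaccard(a, b) == pytest.approx(jaccard_oracle(a, b)) == pytest.approx(1 / 3)

    def test_identical_and_disjoint(self):
        assert pac.jaccard(bits(3, 4), bits(3, 4)) == 1.0
        assert pac.jaccard(bits(0), bits(1)) == 0.0

    def test_both_all_zero_defined_as_one(self):
        assert pac.jaccard(bits(), bits()) == 1.0

    @given(
        st.lists(st.integers(0, 1), min_size=21, max_size=21),
        st.lists(st.integers(0, 1), min_size=21, max_size=21),
    )
    def test_matches_count_oracle_and_is_symmetric(self, a, b):
        a, b = np.array(a, dtype=np.uint8), np.array(b, dtype=np.uint8)
        s = pac.jaccard(a, b)
        assert s == pytest.approx(jaccard_oracle(a, b))
        assert s == pytest.approx(pac.jaccard(b, a))
        assert 0.0 <= s <= 1.0


def exact_score_oracle(test_codes, book_codes):
    """All-pairs comparison: count test frames equal to any codebook code."""
    return sum(1 for t in test_codes for c in {tuple(x) for x in book_codes} if tuple(t) == c)


class TestClassify:
    def test_exact_match_count_example(self):
        a, e = bits(0), bits(1)
        pair = pac.make_unique(
            pac.Codebook({int(pac.pack_codes(a[None])[0]): 1}, "ON", "p"),
            pac.Codebook({int(pac.pack_codes(e[None])[0]): 1}, "OFF", "p"),
        )
        d = pac.classify_sample(np.array([a, a, e]), pair)
        assert (d.label, d.on_score, d.off_score, d.mechanism) == ("ON", 2.0, 1.0, "exact")

    def test_jaccard_fallback_picks_nearer_book(self):
        # test code shares 2 of 3 bits with the OFF code, 1 of 3 with the ON
        on_code, off_code = bits(0, 5, 6), bits(1, 2, 3)
        pair = pac.make_unique(
            pac.Codebook({int(pac.pack_codes(on_code[None])[0]): 1}, "ON", "p"),
            pac.Codebook({int(pac.pack_codes(off_code[None])[0]): 1}, "OFF", "p"),
        )
        test = np.array([bits(1, 2, 9)])
        d = pac.classify_sample(test, pair)
        assert d.mechanism == "jaccard"
        assert d.label == "OFF"
        assert d.off_score == pytest.approx(jaccard_oracle(test[0], off_code))
        assert d.on_score == pytest.approx(jaccard_oracle(test[0], on_code))

    @given(code_arrays, code_arrays, code_arrays)
    def test_exact_scores_equal_brute_force_oracle(self, test, on_rows, off_rows):
        on_codes = {int(c): 1 for c in pac.pack_codes(on_rows)}
        off_codes = {int(c): 1 for c in pac.pack_codes(off_rows)}
        shared = set(on_codes) & set(off_codes)
        on_codes = {c: n for c, n in on_codes.items() if c not in shared}
        off_codes = {c: n for c, n in off_codes.items() if c not in shared}
        if not on_codes and not off_codes:
            return
        pair = pac.UniqueCodebookPair(
            pac.Codebook(on_codes, "ON", "p"), pac.Codebook(off_codes, "OFF", "p")
        )
        d = pac.classify_sample(test, pair)
        on_unique = [pac.unpack_code(c) for c in on_codes]
        off_unique = [pac.unpack_code(c) for c in off_codes]
        on_oracle = exact_score_oracle(test, on_unique) if on_unique else 0
        off_oracle = exact_score_oracle(test, off_unique) if off_unique else 0
        if on_oracle != off_oracle:
            assert d.mechanism == "exact"
            assert (d.on_score, d.off_score) == (on_oracle, off_oracle)
            assert d.label == ("ON" if on_oracle > off_oracle else "OFF")
        else:
            assert d.mechanism == "jaccard"

    @given(code_arrays, code_arrays, code_arrays)
    def test_label_symmetry_under_book_swap(self, test, on_rows, off_rows):
        on_codes = {int(c): 1 for c in pac.pack_codes(on_rows)}
        off_codes = {int(c): 1 for c in pac.pack_codes(off_rows)}
        shared = set(on_codes) & set(off_codes)
        on_codes = {c: n for c, n in on_codes.items() if c not in shared}
        off_codes = {c: n for c, n in off_codes.items() if c not in shared}
        if not on_codes and not off_codes:
            return
        pair = pac.UniqueCodebookPair(
            pac.Codebook(on_codes, "ON", "p"), pac.Codebook(off_codes, "OFF", "p")
        )
        flipped = pac.UniqueCodebookPair(
            pac.Codebook(off_codes, "ON", "p"), pac.Codebook(on_codes, "OFF", "p")
        )
        d1 = pac.classify_sample(test, pair)
        d2 = pac.classify_sample(test, flipped)
        expected = {"ON": "OFF", "OFF": "ON", "ABSTAIN": "ABSTAIN"}[d1.label]
        assert d2.label == expected

    def test_unique_count_mode_collapses_duplicates(self):
        a, e = bits(0), bits(1)
        pair = pac.UniqueCodebookPair(
            pac.Codebook({int(pac.pack_codes(a[None])[0]): 1}, "ON", "p"),
            pac.Codebook({int(pac.pack_codes(e[None])[0]): 1}, "OFF", "p"),
        )
        d = pac.classify_sample(np.array([a, a, a, e]), pair, count_mode="unique")
        assert (d.on_score, d.off_score) == (1.0, 1.0) or d.mechanism == "jaccard"


class TestVoting:
    def mk(self, label, margin=0.0):
        on = max(margin, 0.0)
        off = max(-margin, 0.0)
        return pac.MatchDecision(label, on, off, "exact")

    def test_simple_majority(self):
        assert pac.vote_protocols([self.mk("ON"), self.mk("ON"), self.mk("OFF")]) == "ON"

    def test_margin_breaks_ties(self):
        assert pac.vote_protocols([self.mk("ON", 5.0), self.mk("OFF", -1.0)]) == "ON"
        assert pac.vote_protocols([self.mk("ON", 1.0), self.mk("OFF", -5.0)]) == "OFF"

    def test_abstain_excluded(self):
        assert pac.vote_protocols([self.mk("ABSTAIN"), self.mk("OFF")]) == "OFF"

    def test_all_abstain_undecidable(self):
        with pytest.raises(UndecidableError):
            pac.vote_protocols([self.mk("ABSTAIN"), self.mk("ABSTAIN")])
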
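"""Tandem- and inverted-repeat detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import rand_seq, revcomp, tandem_oracle
from midgemito.repeats import (
    count_variant_copies,
    find_inverted_repeats,
    find_tandem_repeats,
    format_copies,
    group_interrupted,
    minimal_rotation,
    primitive_root,
)
from midgemito.simulate import _array_seq, _build_repeat_locus


def _locus(rng, arrays):
    """Planted arrays with screened, guarded flanks."""
    return _build_repeat_locus(rng, arrays, 0.857)


class TestMotifHelpers:
    @given(st.text(alphabet="ACGT", min_size=1, max_size=12), st.integers(0, 11))
    def test_minimal_rotation_invariant_under_rotation(self, m, k):
        k %= len(m)
        assert minimal_rotation(m) == minimal_rotation(m[k:] + m[:k])

    def test_primitive_root(self):
        assert primitive_root("ATAT") == "AT"
        assert primitive_root("TAAAA") == "TAAAA"

    def test_copy_notation(self):
        assert format_copies(25.0) == "25"
        assert format_copies(5.42) == "5.4"


class TestTandemDetection:
    def test_perfect_pentamer_array(self, rng):
        locus, spans = _locus(rng, [(_array_seq("TAAAA", 25), 5)])
        hits = find_tandem_repeats(locus)
        assert len(hits) == 1
        h = hits[0]
        assert (h.phase, h.period, h.copies, h.identity) == ("TAAAA", 5, 25.0, 1.0)
        assert (h.start, h.end) == spans[0][:2]

    def test_fractional_copies_of_twelve_mer(self, rng):
        arr = "ATTTATATTTAA" * 5 + "ATTTA"
        locus, spans = _locus(rng, [(arr, 12)])
        (h,) = [h for h in find_tandem_repeats(locus) if h.period == 12]
        assert h.copies == 5.4                       # 65 / 12 = 5.42 -> 5.4

    def test_homopolymer_gives_no_hit_at_min_period_two(self):
        assert find_tandem_repeats("G" + "A" * 40 + "C", min_period=2) == []

    def test_copies_span_consistency(self, rng):
        locus, _ = _locus(rng, [(_array_seq("AATGT", 9.4), 5)])
        for h in find_tandem_repeats(locus):
            assert abs((h.end - h.start) / h.period - h.copies) <= 0.05

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("")

    def test_exact_mode_equals_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = rand_seq(rng, 300)
            detected = sorted(
                (h.start, h.end, h.period)
                for h in find_tandem_repeats(s, 2, 12, 3, max_mismatch_frac=0.0)
            )
            assert detected == tandem_oracle(s)

    def test_planted_array_recovery_exact(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            p = int(rng.integers(2, 13))
            copies = int(rng.integers(3, 61))
            while True:
                motif = rand_seq(rng, p)
                if primitive_root(motif) == motif:
                    break
            locus, spans = _build_repeat_locus(
                rng, [(_array_seq(motif, float(copies)), p)], 0.857, spacer_len=30
            )
            hits = find_tandem_repeats(locus, 2, 12)
            assert any(
                h.period == p
                and (h.start, h.end) == spans[0][:2]
                and h.copies == copies
                for h in hits
            )

    def test_rotation_stability_for_circular_input(self, rng):
        locus, spans = _locus(rng, [(_array_seq("TAAAA", 20), 5)])
        (h0,) = find_tandem_repeats(locus)
        k = 10                       # cut inside the leading spacer
        rotated = locus[k:] + locus[:k]
        (h1,) = find_tandem_repeats(rotated)
        assert (h1.start, h1.end) == (h0.start - k, h0.end - k)
        assert (h1.phase, h1.copies) == (h0.phase, h0.copies)


class TestInterruptedArrays:
    def test_composite_notation(self, rng):
        locus, _ = _locus(
            rng,
            [(_array_seq("TAAAA", 11), 5), (_array_seq("TAAAA", 5), 5)],
        )
        hits = find_tandem_repeats(locus)
        (array,) = group_interrupted(hits, locus)
        assert array.notation == "11+5"
        assert array.total_copies == 16.0

    def test_singleton_and_distinct_motifs(self, rng):
        locus, _ = _locus(
            rng, [(_array_seq("TAAAA", 25), 5), (_array_seq("AAATT", 49), 5)]
        )
        arrays = group_interrupted(find_tandem_repeats(locus), locus)
        assert sorted(a.notation for a in arrays) == ["25", "49"]
        assert {a.motif for a in arrays} == {"TAAAA", "AAATT"}

    def test_distant_hits_stay_separate(self, rng):
        locus, _ = _locus(
            rng,
            [(_array_seq("TAAAA", 6), 5), (_array_seq("TAAAA", 7), 5)],
        )
        hits = find_tandem_repeats(locus)
        assert len(group_interrupted(hits, locus, max_gap=200)) == 1
        assert len(group_interrupted(hits, locus, max_gap=10)) == 2


class TestVariantCopies:
    def test_two_substituted_copies_detected_in_one_array(self, rng):
        motif, variant = "ATTTATATTTAA", "ATTTATATCTAA"
        arr = motif * 2 + variant * 2 + motif + motif[:5]
        locus, spans = _locus(rng, [(arr, 12)])
        (h,) = [h for h in find_tandem_repeats(locus) if h.period == 12]
        assert (h.start, h.end) == spans[0][:2]
        assert h.copies == 5.4
        assert h.variant_copies == 2
        assert count_variant_copies(h, locus, variant) == 2

    def test_perfect_array_has_no_variants(self, rng):
        locus, _ = _locus(rng, [(_array_seq("ATTTATATTTAA", 5.0), 12)])
        (h,) = [h for h in find_tandem_repeats(locus) if h.period == 12]
        assert h.variant_copies == 0

    def test_all_copies_variant(self, rng):
        variant = "ATTTATATCTAA"
        locus, _ = _locus(rng, [(variant * 4, 12)])
        (h,) = [h for h in find_tandem_repeats(locus) if h.period == 12]
        assert count_variant_copies(h, locus, variant) == 4

    def test_length_mismatch_rejected(self, rng):
        locus, _ = _locus(rng, [(_array_seq("TAAAA", 5), 5)])
        (h,) = find_tandem_repeats(locus)
        with pytest.raises(ValueError):
            count_variant_copies(h, locus, "TAAAAT")


class TestInvertedRepeats:
    def test_planted_144bp_arm_pair(self):
        rng = np.random.default_rng(5)
        arm = rand_seq(rng, 144)
        s = rand_seq(rng, 100) + "CC" + arm + rand_seq(rng, 50) \
            + revcomp(arm) + "CC" + rand_seq(rng, 100)
        pairs = find_inverted_repeats(s, max_mismatch_frac=0.0)
        assert pairs
        (a1, b1), (a2, b2) = pairs[0]
        assert b1 - a1 >= 144
        assert a1 <= 102 and b1 >= 102 + 144      # planted arm covered

    def test_random_sequence_typically_empty(self):
        rng = np.random.default_rng(6)
        hits = sum(
            bool(find_inverted_repeats(rand_seq(rng, 500), min_len=30))
            for _ in range(10)
        )
        assert hits == 0

    def test_palindrome_hairpin_limit(self):
        rng = np.random.default_rng(7)
        pal = rand_seq(rng, 40)
        s = rand_seq(rng, 30) + pal + revcomp(pal) + rand_seq(rng, 30)
        pairs = find_inverted_repeats(s, min_len=30, max_mismatch_frac=0.0)
        assert pairs
        (a1, b1), (a2, b2) = pairs[0]
        assert b1 == a2                           # zero spacer
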
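"""Signed circular gene-order comparison."""

import itertools

import numpy as np
import pytest

from oracles import conserved_oracle
from midgemito import reference as ref
from midgemito.geneorder import (
    CONSERVED,
    LOCAL_INVERSION,
    REMOTE_INVERSION,
    TRANSLOCATION,
    SignedGeneOrder,
    breakpoint_distance,
    classify_rearrangements,
    conserved_boundaries,
    find_conserved_blocks,
    oriented_adjacencies,
)

O = SignedGeneOrder.from_pairs


def _random_signed_order(rng, names):
    perm = list(names)
    rng.shuffle(perm)
    return O([(g, "+-"[rng.integers(0, 2)]) for g in perm])


class TestAdjacencies:
    def test_three_gene_circle_has_three_adjacencies(self):
        assert len(oriented_adjacencies(O([("A", "+"), ("B", "+"), ("C", "+")]))) == 3

    def test_reading_direction_symmetry(self):
        a = oriented_adjacencies(O([("A", "+"), ("B", "+")]))
        b = oriented_adjacencies(O([("B", "-"), ("A", "-")]))
        assert a == b

    def test_identity_order_shares_all_n_adjacencies(self):
        order = O([(f"g{i}", "+") for i in range(7)])
        count, _ = conserved_boundaries(order, order)
        assert count == 7

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            O([("A", "+"), ("A", "-")])


class TestConservedBoundaries:
    def test_single_in_place_inversion_keeps_three_of_five(self):
        r = O([(g, "+") for g in "ABCDE"])
        q = O([("A", "+"), ("B", "+"), ("C", "-"), ("D", "+"), ("E", "+")])
        count, listing = conserved_boundaries(q, r)
        assert count == 3 and len(listing) == 3
        assert breakpoint_distance(q, r) == 2

    def test_universe_mismatch_reports_difference(self):
        r = O([("A", "+"), ("B", "+"), ("C", "+")])
        q = O([("A", "+"), ("B", "+"), ("D", "+")])
        with pytest.raises(ValueError, match="D"):
            conserved_boundaries(q, r)

    def test_rotation_invariance(self, rng):
        names = [f"g{i}" for i in range(8)]
        r = _random_signed_order(rng, names)
        q = _random_signed_order(rng, names)
        base = conserved_boundaries(q, r)[0]
        for k in (1, 3, 5):
            assert conserved_boundaries(q.rotated(k), r)[0] == base
            assert conserved_boundaries(q, r.rotated(k))[0] == base

    def test_reading_direction_invariance(self, rng):
        names = [f"g{i}" for i in range(8)]
        for _ in range(20):
            r = _random_signed_order(rng, names)
            q = _random_signed_order(rng, names)
            assert (
                conserved_boundaries(q.reversed_reading(), r)[0]
                == conserved_boundaries(q, r)[0]
            )

    def test_breakpoint_distance_symmetric(self, rng):
        names = [f"g{i}" for i in range(7)]
        for _ in range(100):
            q = _random_signed_order(rng, names)
            r = _random_signed_order(rng, names)
            assert breakpoint_distance(q, r) == breakpoint_distance(r, q)

    def test_equals_oracle_on_all_signed_circular_permutations(self):
        """Exhaustive agreement with the plain neighbour-pair oracle, n<=5."""
        for n in (3, 4, 5):
            names = [chr(65 + i) for i in range(n)]
            reference = O([(g, "+") for g in names])
            ref_pairs = [(g, "+") for g in names]
            for perm in itertools.permutations(names[1:]):
                order_names = [names[0], *perm]
                for signs in itertools.product("+-", repeat=n):
                    pairs = list(zip(order_names, signs))
                    got = conserved_boundaries(O(pairs), reference)[0]
                    assert got == conserved_oracle(pairs, ref_pairs)


class TestClassification:
    def test_identity_all_conserved(self):
        r = O([(g, "+") for g in "ABCDE"])
        rep = classify_rearrangements(r, r)
        assert set(rep.per_gene.values()) == {CONSERVED}
        assert rep.breakpoints == 0

    def test_local_inversion(self):
        r = O([(g, "+") for g in "ABCDE"])
        q = O([("A", "+"), ("B", "+"), ("C", "-"), ("D", "+"), ("E", "+")])
        rep = classify_rearrangements(q, r)
        assert rep.per_gene["C"] == LOCAL_INVERSION
        assert all(v == CONSERVED for g, v in rep.per_gene.items() if g != "C")

    def test_swap_two_nonadjacent_genes(self):
        r = O([(g, "+") for g in "ABCDEF"])
        q = O([("A", "+"), ("E", "+"), ("C", "+"), ("D", "+"), ("B", "+"), ("F", "+")])
        rep = classify_rearrangements(q, r)
        assert rep.per_gene["B"] == rep.per_gene["E"] == TRANSLOCATION
        assert all(
            v == CONSERVED for g, v in rep.per_gene.items() if g not in "BE"
        )

    def test_moved_and_flipped_is_remote_inversion(self):
        r = O([(g, "+") for g in "ABCDEF"])
        q = O([("A", "+"), ("B", "+"), ("D", "+"), ("E", "+"), ("C", "-"), ("F", "+")])
        rep = classify_rearrangements(q, r)
        assert rep.per_gene["C"] == REMOTE_INVERSION

    def test_classes_invariant_under_reading_direction(self, rng):
        names = [f"g{i}" for i in range(8)]
        for _ in range(10):
            r = _random_signed_order(rng, names)
            q = _random_signed_order(rng, names)
            a = classify_rearrangements(q, r).per_gene
            b = classify_rearrangements(q.reversed_reading(), r).per_gene
            assert a == b


class TestBlocks:
    def test_signed_inversion_block(self):
        r = O([("A", "+"), ("B", "+"), ("C", "+"), ("D", "+")])
        q = O([("C", "-"), ("B", "-"), ("A", "-"), ("D", "+")])
        blocks = find_conserved_blocks(q, r)
        inv = [b for b in blocks if b.inverted]
        assert any(set(b.genes) == {"A", "B", "C"} for b in inv)

    def test_identity_is_one_whole_circle_block(self):
        r = O([(g, "+") for g in "ABCDE"])
        (block,) = find_conserved_blocks(r, r)
        assert set(block.genes) == set("ABCDE") and not block.inverted

    def test_published_pcg_trna_block_reported_inverted(self):
        q = O(ref.oryzae_gene_order())
        r = O(ref.ANCESTRAL_GENE_ORDER)
        blocks = find_conserved_blocks(q, r, ignore_orientation=True)
        target = {"ATP8", "ATP6", "COIII", "trnG", "ND3"}
        assert any(set(b.genes) == target and b.inverted for b in blocks)

    def test_published_trna_block_reported_inverted(self):
        q = O(ref.oryzae_gene_order())
        r = O(ref.ANCESTRAL_GENE_ORDER)
        blocks = find_conserved_blocks(q, r, ignore_orientation=True)
        target = {"trnF", "trnE", "trnS1", "trnN", "trnR"}
        assert any(set(b.genes) == target and b.inverted for b in blocks)


class TestFullReport:
    def test_report_is_self_consistent(self):
        q = O(ref.oryzae_gene_order())
        r = O(ref.ANCESTRAL_GENE_ORDER)
        rep = classify_rearrangements(q, r)
        assert len(rep.per_gene) == 38            # 37 genes + CR marker
        assert rep.breakpoints == 38 - rep.conserved_boundaries
        assert rep.conserved_boundaries <= rep.conserved_boundaries_unsigned
        # category split covers every gene exactly once
        assert sum(sum(v.values()) for v in rep.category_counts.values()) == 38

    def test_trna_and_pcg_rearrangements_reported(self):
        q = O(ref.oryzae_gene_order())
        r = O(ref.ANCESTRAL_GENE_ORDER)
        rep = classify_rearrangements(q, r)
        moved_trnas = rep.rearranged_genes(categories=["tRNA"])
        moved_pcgs = rep.rearranged_genes(categories=["PCG"])
        # the gall-midge genome is heavily rearranged in both gene classes
        assert len(moved_trnas) >= 10 and len(moved_pcgs) >= 5
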
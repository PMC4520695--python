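"""Composition, strand skew and RSCU statistics."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from midgemito.composition import (
    at_content_from_percentages,
    base_composition,
    codon_usage,
    feature_composition_table,
    round_half_away,
    rscu_from_counts,
    sense_codons,
    skew_from_percentages,
    strand_share_percent,
    synonymous_families,
)
from midgemito.model import (
    GeneAnnotation,
    MitogenomeRecord,
    NucleotideSequence,
    reverse_complement,
)
from midgemito.reference import COMPOSITION_TABLE, SELF_CONSISTENT_AT_SKEW_ROWS

dna = st.text(alphabet="ACGT", min_size=4, max_size=300)


class TestBaseComposition:
    def test_symmetric_sequence(self):
        c = base_composition("AATT")
        assert (c.pctA, c.pctT, c.at_skew) == (50.0, 50.0, 0.0)

    def test_hand_arithmetic(self):
        assert base_composition("GGC").gc_skew == 0.33      # (2-1)/3
        assert base_composition("AAAT").at_skew == 0.5      # (3-1)/4

    def test_n_bases_excluded_from_denominator(self):
        c = base_composition("AANN")
        assert c.pctA == 100.0
        with pytest.raises(ValueError):
            base_composition("NNN")

    @given(dna)
    def test_skew_antisymmetry_under_reverse_complement(self, s):
        fwd, rev = base_composition(s), base_composition(reverse_complement(s))
        if fwd.at_skew is not None:
            assert fwd.at_skew == -rev.at_skew or (fwd.at_skew == 0 == rev.at_skew)
        if fwd.gc_skew is not None:
            assert fwd.gc_skew == -rev.gc_skew or (fwd.gc_skew == 0 == rev.gc_skew)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.125, 2) == 0.13
        assert round_half_away(-0.125, 2) == -0.13
        assert round_half_away(94.45, 1) == 94.5


class TestSkewFromPrintedPercentages:
    @pytest.mark.parametrize("row", SELF_CONSISTENT_AT_SKEW_ROWS)
    def test_published_at_skews_recompute(self, row):
        _, a, _, _, t, _, at_skew, _ = COMPOSITION_TABLE[row]
        assert skew_from_percentages(a, t) == at_skew

    def test_published_whole_genome_gc_skew(self):
        _, _, c, g, _, _, _, gc_skew = COMPOSITION_TABLE["whole_genome"]
        assert skew_from_percentages(g, c) == gc_skew == -0.13

    def test_equal_percentages_and_zero_denominator(self):
        assert skew_from_percentages(21.7, 21.7) == 0.0
        assert skew_from_percentages(0.0, 0.0) is None

    def test_at_content_sums(self):
        assert at_content_from_percentages(51.0, 43.5) == 94.5


class TestFeatureTable:
    def test_single_feature_equals_whole_genome(self):
        rec = MitogenomeRecord(
            id="r",
            sequence=NucleotideSequence("ATATGCATAT"),
            features=[GeneAnnotation("COI", "PCG", "J", 0, 10)],
        )
        df = feature_composition_table(rec).set_index("feature")
        whole = df.loc["whole_genome"]
        coi = df.loc["COI"]
        assert (whole.drop("feature", errors="ignore") == coi).all()

    def test_pure_at_feature(self):
        rec = MitogenomeRecord(
            id="r",
            sequence=NucleotideSequence("ATATATATGC"),
            features=[GeneAnnotation("16S", "rRNA", "J", 0, 8)],
        )
        df = feature_composition_table(rec).set_index("feature")
        assert df.loc["16S", "at_content"] == 100.0

    def test_pcg_aggregate_length_is_sum_of_pcg_lengths(self, gmb1):
        record, _ = gmb1
        df = feature_composition_table(record).set_index("feature")
        expected = sum(f.size for f in record.features if f.category == "PCG")
        assert df.loc["PCGs", "length"] == expected

    def test_requires_features(self):
        rec = MitogenomeRecord(id="r", sequence=NucleotideSequence("ACGT"))
        with pytest.raises(ValueError):
            feature_composition_table(rec)


def _pcg_record(coding: str) -> MitogenomeRecord:
    return MitogenomeRecord(
        id="r",
        sequence=NucleotideSequence(coding),
        features=[
            GeneAnnotation("COI", "PCG", "J", 0, len(coding),
                           start_codon=coding[:3], stop_codon=coding[-3:])
        ],
    )


class TestCodonUsage:
    def test_62_sense_codons_in_invertebrate_code(self):
        assert len(sense_codons()) == 62
        fams = synonymous_families()
        assert sorted(fams["L"]) == ["CTA", "CTC", "CTG", "CTT", "TTA", "TTG"]
        assert len(fams["S"]) == 8      # AGN codes serine in this code

    def test_uniform_family_rscu_one(self):
        rec = _pcg_record("ATT" + "TTT" + "TTC" + "TTT" + "TTC" + "TAA")
        table = codon_usage(rec)
        assert table.rscu["TTT"] == table.rscu["TTC"] == 1.0
        assert table.counts["TTT"] == 2
        # the stop codon is excluded from the totals
        assert table.total == 5

    def test_exclusive_codon_gets_family_size(self):
        rec = _pcg_record("ATG" + "GCT" * 4 + "TAA")
        rscu = codon_usage(rec).rscu
        assert rscu["GCT"] == 4.0
        assert rscu["GCC"] == rscu["GCA"] == rscu["GCG"] == 0.0

    def test_strand_scopes_partition_total(self, gmb1):
        record, _ = gmb1
        full = codon_usage(record)
        j = codon_usage(record, "J_strand")
        n = codon_usage(record, "N_strand")
        assert j.total + n.total == full.total
        for codon in full.counts:
            assert j.counts[codon] + n.counts[codon] == full.counts[codon]

    def test_rscu_family_sums_equal_family_size(self, gmb1):
        record, _ = gmb1
        table = codon_usage(record)
        for aa, codons in synonymous_families().items():
            if sum(table.counts[c] for c in codons):
                assert sum(table.rscu[c] for c in codons) == pytest.approx(len(codons))

    def test_trailing_remainder_dropped_with_warning(self):
        rec = _pcg_record("ATT" + "TTT" + "TAA" + "GC")
        with pytest.warns(UserWarning, match="divisible"):
            table = codon_usage(rec)
        assert table.total == 2

    def test_published_strand_share(self):
        assert strand_share_percent(2209, 3573) == 61.8


def test_generated_genomes_recover_target_at(rng):
    """Whole-genome A+T lands within +-1 pp of the requested target."""
    from midgemito.simulate import SyntheticGenomeSpec, generate_mitogenome

    for seed in range(5):
        _, truth = generate_mitogenome(
            SyntheticGenomeSpec(biotype="GMB2", seed=1000 + seed)
        )
        assert abs(truth["at_realized"] - 0.857) < 0.01
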
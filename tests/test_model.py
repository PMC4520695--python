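"""Genome record model, coordinate conventions and file round trips."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from midgemito import model
from midgemito.model import (
    GeneAnnotation,
    MitogenomeRecord,
    NucleotideSequence,
    ParseError,
    extract_feature_sequence,
    linearize,
    read_fasta,
    read_feature_table,
    reverse_complement,
    write_feature_table,
    write_gff3,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestNucleotideSequence:
    def test_case_normalized_and_validated(self):
        assert NucleotideSequence("acgtn").residues == "ACGTN"
        with pytest.raises(ValueError):
            NucleotideSequence("")
        with pytest.raises(ValueError):
            NucleotideSequence("ACGU")

    @given(dna)
    def test_reverse_complement_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s

    def test_circular_span_wraps_origin(self):
        seq = NucleotideSequence("ACGTACGTAA", is_circular=True)
        assert seq.span(8, 13) == "AAACG"
        linear = NucleotideSequence("ACGTACGTAA")
        with pytest.raises(ValueError):
            linear.span(8, 13)


class TestFastaIO:
    def test_minimal_circular_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">g circular\nACGT\n")
        (rec,) = read_fasta(p)
        assert len(rec.sequence) == 4 and rec.sequence.is_circular

    def test_multi_record_and_case(self, tmp_path):
        p = tmp_path / "m.fa"
        p.write_text(">a\nac\n>b\ngt\n")
        recs = read_fasta(p)
        assert [r.sequence.residues for r in recs] == ["AC", "GT"]
        assert not recs[0].sequence.is_circular

    def test_errors_name_the_problem(self, tmp_path):
        empty = tmp_path / "e.fa"
        empty.write_text("")
        with pytest.raises(ParseError, match="empty"):
            read_fasta(empty)
        bad = tmp_path / "b.fa"
        bad.write_text(">x\nACGU\n")
        with pytest.raises(ParseError, match=":2"):
            read_fasta(bad)


HEADER = "\t".join(model.FEATURE_TABLE_COLUMNS)


def _table(tmp_path, *rows):
    p = tmp_path / "t.tsv"
    p.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return p


class TestFeatureTable:
    def test_published_style_rows(self, tmp_path):
        p = _table(
            tmp_path,
            "trnQ\ttRNA\tJ\t0\t56\tTTG\t-\t-\t3",
            "ND2\tPCG\tN\t121\t1090\t-\tATT\tTAA\t-",
        )
        trnq, nd2 = read_feature_table(p)
        assert trnq.size == 56 and trnq.anticodon == "TTG"
        assert nd2.size == 969 and nd2.category == "PCG" and nd2.stop_codon == "TAA"

    @pytest.mark.parametrize(
        "row",
        [
            "trnQ\ttRNA\tX\t0\t56\tTTG\t-\t-\t-",       # bad strand
            "NADH9\tPCG\tJ\t0\t99\t-\tATT\tTAA\t-",      # unknown gene
            "trnQ\ttRNA\tJ\tzero\t56\tTTG\t-\t-\t-",     # non-integer coords
        ],
    )
    def test_rejects_malformed_rows(self, tmp_path, row):
        with pytest.raises((ParseError, ValueError)):
            read_feature_table(_table(tmp_path, row))

    def test_write_read_identity(self, tmp_path, gmb1):
        record, _ = gmb1
        p = tmp_path / "rt.tsv"
        write_feature_table(record, p)
        assert read_feature_table(p) == record.features


class TestExtraction:
    def test_minus_strand_is_reverse_complemented(self):
        rec = MitogenomeRecord(
            id="r",
            sequence=NucleotideSequence("ATGC"),
            features=[GeneAnnotation("COI", "PCG", "N", 0, 4)],
        )
        assert str(extract_feature_sequence(rec, rec.features[0])) == "GCAT"

    def test_origin_spanning_feature(self):
        rec = MitogenomeRecord(
            id="r",
            sequence=NucleotideSequence("AAAAAAAACG", is_circular=True),
            features=[GeneAnnotation("COI", "PCG", "J", 8, 13)],
        )
        assert str(extract_feature_sequence(rec, rec.features[0])) == "CGAAA"

    def test_synthetic_pcgs_have_annotated_codons(self, gmb1):
        record, _ = gmb1
        for f in record.features:
            if f.category != "PCG":
                continue
            s = str(extract_feature_sequence(record, f))
            assert s.startswith(f.start_codon)
            assert s.endswith(f.stop_codon)


class TestLinearize:
    def test_identity_when_origin_already_zero(self, gmb1):
        record, _ = gmb1
        lin = linearize(record, record.features[0].name)
        assert lin.sequence.residues == record.sequence.residues
        assert lin.features == record.features

    def test_rotation_inverse(self, gmb1):
        record, _ = gmb1
        n = len(record.sequence)
        back = model.rotate(model.rotate(record, 1234), n - 1234)
        assert back.sequence.residues == record.sequence.residues
        assert back.features == record.features

    def test_published_gene_order_reproduced(self, gmb1):
        record, _ = gmb1
        lin = linearize(record, "trnQ")
        names = lin.feature_names()
        assert names[0] == "trnQ"
        assert names[-1] == "CR" and names[-2] == "12S"
        with pytest.raises(KeyError):
            linearize(record, "nosuchgene")


class TestGff3:
    def test_conventions(self, tmp_path):
        rec = MitogenomeRecord(
            id="g",
            sequence=NucleotideSequence("A" * 100),
            features=[
                GeneAnnotation("trnQ", "tRNA", "J", 0, 56, anticodon="TTG"),
                GeneAnnotation("ND2", "PCG", "N", 60, 90),
            ],
        )
        p = tmp_path / "g.gff3"
        write_gff3(rec, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        cols_q = lines[2].split("\t")
        cols_n = lines[3].split("\t")
        assert (cols_q[3], cols_q[4], cols_q[6]) == ("1", "56", "+")
        assert cols_n[6] == "-"

    def test_coordinate_round_trip_1000_random_features(self, rng, tmp_path):
        feats = []
        used = set()
        for _ in range(1000):
            start = int(rng.integers(0, 5000))
            end = start + int(rng.integers(1, 300))
            name = f"f{len(feats)}"
            feats.append(("spacer", start, end, name))
        rec = MitogenomeRecord(
            id="g",
            sequence=NucleotideSequence("A" * 5300),
            features=[
                GeneAnnotation(name, "spacer", "J", s, e)
                for _, s, e, name in feats
            ],
        )
        p = tmp_path / "big.gff3"
        write_gff3(rec, p)
        body = [l.split("\t") for l in p.read_text().splitlines()[2:]]
        for cols, f in zip(body, rec.features):
            assert int(cols[3]) - 1 == f.start and int(cols[4]) == f.end


class TestInvariants:
    def test_extracted_length_matches_span(self, gmb1):
        record, _ = gmb1
        for f in record.features:
            assert len(extract_feature_sequence(record, f)) == f.size

    def test_duplicate_gene_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MitogenomeRecord(
                id="r",
                sequence=NucleotideSequence("ACGTACGT"),
                features=[
                    GeneAnnotation("COI", "PCG", "J", 0, 3),
                    GeneAnnotation("COI", "PCG", "J", 4, 7),
                ],
            )

    def test_anticodon_only_on_trnas(self):
        with pytest.raises(ValueError):
            GeneAnnotation("COI", "PCG", "J", 0, 9, anticodon="TTG")
        with pytest.raises(ValueError):
            GeneAnnotation("trnQ", "tRNA", "J", 0, 56)
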
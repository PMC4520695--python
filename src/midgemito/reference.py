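"""Published reference values for the *Orseolia oryzae* (Asian rice gall
midge) mitogenome and the ancestral insect gene order.

These constants transcribe the published annotation of the gall-midge
mitogenome: the gene order and strands, per-gene sizes, anticodons, start and
stop codons and variable-arm lengths; the per-feature nucleotide composition
table; and the repeat-iteration counts that distinguish the gall-midge
biotypes and the two other *Orseolia* species. They are data fixtures - every
statistic in this package is recomputed from sequence, these tables only
parameterize the synthetic genomes and provide the printed values that the
published analysis reports.

Notes on the source annotation:

* The annotation table prints "-" for ATP6/ATP8 codons and TAA for ND6; the
  composition table (which carries codons for all 13 PCGs, ATP6=ATG/TAA,
  ATP8=ATA/TAA, ND6=ATA/TAG) is used here, consistent with the stated codon
  tallies (one ATG / seven ATT / five ATA starts; twelve TAA / one TAG stops).
* ``GMB4`` RR-I counts "30-33", ``GMB4M`` "28-37" and ``GMB6`` "5-7"/"52-58"
  are printed as ranges (observed heteroplasmy); they are kept as closed
  intervals.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Gall-midge mitogenome annotation (gene order on the circle, J-strand
# reading, control region last). Columns: name, category, strand, size (bp),
# anticodon, start codon, stop codon, variable-arm length ("TV" = the T-arm
# and variable arm are replaced by a single TV loop).
# ---------------------------------------------------------------------------

ORYZAE_ANNOTATION = [
    # name, category, strand, size, anticodon, start, stop, variable arm
    ("trnQ",  "tRNA", "J",   56, "TTG", None,  None,  3),
    ("trnM",  "tRNA", "N",   65, "CAT", None,  None,  9),
    ("ND2",   "PCG",  "N",  969, None,  "ATT", "TAA", None),
    ("trnW",  "tRNA", "N",   64, "TCA", None,  None,  "TV"),
    ("RR-I",  "repeat_region", "J", 0, None, None, None, None),
    ("trnA",  "tRNA", "N",   58, "TGC", None,  None,  "TV"),
    ("trnI",  "tRNA", "N",   67, "AAT", None,  None,  5),
    ("RR-II", "repeat_region", "J", 0, None, None, None, None),
    ("COI",   "PCG",  "N", 1539, None,  "ATT", "TAA", None),
    ("trnF",  "tRNA", "N",   71, "GAA", None,  None,  5),
    ("trnE",  "tRNA", "J",   77, "TTC", None,  None,  8),
    ("trnS1", "tRNA", "J",   98, "TCT", None,  None,  4),
    ("trnN",  "tRNA", "N",   64, "ATT", None,  None,  6),
    ("trnR",  "tRNA", "J",   73, "TCG", None,  None,  6),
    ("trnC",  "tRNA", "N",   77, "GCA", None,  None,  4),
    ("trnY",  "tRNA", "J",   58, "ATA", None,  None,  0),
    ("ND3",   "PCG",  "J",  342, None,  "ATT", "TAA", None),
    ("trnG",  "tRNA", "J",   77, "TCC", None,  None,  6),
    ("COIII", "PCG",  "J",  780, None,  "ATT", "TAA", None),
    ("ATP6",  "PCG",  "J",  678, None,  "ATG", "TAA", None),
    ("ATP8",  "PCG",  "J",  147, None,  "ATA", "TAA", None),
    ("trnK",  "tRNA", "J",   61, "TTT", None,  None,  10),
    ("COII",  "PCG",  "J",  669, None,  "ATT", "TAA", None),
    ("trnD",  "tRNA", "J",   66, "GTC", None,  None,  5),
    ("trnL2", "tRNA", "J",   73, "TAA", None,  None,  15),
    ("ND5",   "PCG",  "J", 1698, None,  "ATA", "TAA", None),
    ("trnH",  "tRNA", "J",   85, "GTG", None,  None,  18),
    ("ND4",   "PCG",  "J", 1185, None,  "ATA", "TAA", None),
    ("ND4L",  "PCG",  "J",  300, None,  "ATT", "TAA", None),
    ("trnP",  "tRNA", "J",   79, "TGT", None,  None,  8),
    ("trnT",  "tRNA", "N",   68, "TGG", None,  None,  0),
    ("ND6",   "PCG",  "N",  456, None,  "ATA", "TAG", None),
    ("CytB",  "PCG",  "N", 1128, None,  "ATT", "TAA", None),
    ("trnS2", "tRNA", "N",   54, "TGA", None,  None,  9),
    ("ND1",   "PCG",  "J",  903, None,  "ATA", "TAA", None),
    ("trnL1", "tRNA", "J",   70, "TAA", None,  None,  5),
    ("16S",   "rRNA", "J", 1262, None,  None,  None,  None),
    ("trnV",  "tRNA", "J",   60, "TAC", None,  None,  4),
    ("12S",   "rRNA", "J",  726, None,  None,  None,  None),
    ("CR",    "control_region", "J", 578, None, None, None, None),
]

#: tRNAs with the D-arm missing / the T-arm plus variable arm replaced by a
#: TV loop / a markedly shortened T-arm, per the published structure calls.
D_ARM_MISSING = ("trnV", "trnN")
TV_LOOP = ("trnW", "trnA")
SHORT_T_ARM = ("trnQ",)

#: Published total genome length and A+T fraction.
GENOME_LENGTH = 15286
GENOME_AT_FRACTION = 0.857

#: Whole-genome marginal base composition (fractions).
BASE_COMPOSITION = {"A": 0.474, "T": 0.383, "C": 0.081, "G": 0.062}


def oryzae_gene_order():
    """Signed circular gene order of the gall-midge mitogenome.

    Repeat regions are positional markers, not genes, and are excluded;
    the control region is included as a positional marker.
    """
    return [
        (name, "+" if strand == "J" else "-")
        for name, cat, strand, *_ in ORYZAE_ANNOTATION
        if cat != "repeat_region"
    ]


# ---------------------------------------------------------------------------
# Ancestral insect (Drosophila-like) mitogenome order. Orientation "+" means
# the ancestral major strand; minor-strand genes are the four PCGs
# ND1/ND4/ND4L/ND5, both rRNAs and the tRNA set {Q, C, Y, F, H, P, L1, V}.
# ---------------------------------------------------------------------------

ANCESTRAL_GENE_ORDER = [
    ("trnI", "+"), ("trnQ", "-"), ("trnM", "+"), ("ND2", "+"), ("trnW", "+"),
    ("trnC", "-"), ("trnY", "-"), ("COI", "+"), ("trnL2", "+"), ("COII", "+"),
    ("trnK", "+"), ("trnD", "+"), ("ATP8", "+"), ("ATP6", "+"), ("COIII", "+"),
    ("trnG", "+"), ("ND3", "+"), ("trnA", "+"), ("trnR", "+"), ("trnN", "+"),
    ("trnS1", "+"), ("trnE", "+"), ("trnF", "-"), ("ND5", "-"), ("trnH", "-"),
    ("ND4", "-"), ("ND4L", "-"), ("trnT", "+"), ("trnP", "-"), ("ND6", "+"),
    ("CytB", "+"), ("trnS2", "+"), ("ND1", "-"), ("trnL1", "-"), ("16S", "-"),
    ("trnV", "-"), ("12S", "-"), ("CR", "+"),
]

# ---------------------------------------------------------------------------
# Published per-feature nucleotide composition (percentages as printed;
# skews as printed; the control region is listed with its table length).
# ---------------------------------------------------------------------------

COMPOSITION_TABLE = {
    # name: (length, A%, C%, G%, T%, A+T%, AT skew, GC skew)
    "whole_genome":   (15286, 47.4, 8.1, 6.2, 38.3, 85.7, 0.12, -0.13),
    "J_strand":       (4093, 37.1, 9.3, 8.5, 45.1, 82.2, -0.10, -0.50),
    "N_strand":       (6677, 53.1, 9.2, 6.8, 30.9, 84.0, -0.26, 0.15),
    "PCGs":           (10727, 43.2, 8.7, 8.0, 40.1, 83.3, 0.04, -0.04),
    "tRNAs":          (1552, 50.3, 4.8, 3.0, 41.9, 92.2, 0.09, -0.23),
    "N_strand_tRNAs": (585, 48.5, 3.8, 3.6, 44.1, 92.6, 0.05, -0.02),
    "J_strand_tRNAs": (967, 51.3, 5.5, 2.7, 40.5, 91.8, -0.12, 0.34),
    "ATP6":           (678, 54.0, 6.2, 7.8, 32.0, 86.0, 0.26, 0.12),
    "ATP8":           (147, 51.0, 3.4, 2.0, 43.5, 94.5, 0.08, 0.09),
    "COI":            (1539, 35.7, 11.9, 11.8, 40.7, 76.4, -0.07, -0.05),
    "COII":           (669, 48.8, 9.9, 9.4, 32.7, 81.5, 0.19, -0.02),
    "COIII":          (780, 53.1, 10.6, 8.7, 27.6, 80.7, 0.32, -0.1),
    "CytB":           (1128, 36.0, 9.6, 9.5, 44.9, 80.9, -0.11, -0.004),
    "ND1":            (903, 53.5, 9.6, 6.7, 30.3, 83.8, 0.28, -0.18),
    "ND2":            (969, 39.5, 6.8, 3.8, 49.8, 89.3, -0.12, -0.28),
    "ND3":            (342, 56.7, 6.7, 5.8, 30.7, 87.4, 0.31, -0.05),
    "ND4":            (1185, 51.6, 10.5, 6.4, 31.4, 83.0, 0.25, -0.24),
    "ND4L":           (300, 54.4, 8.0, 3.0, 35.0, 89.4, 0.22, -0.45),
    "ND5":            (1698, 54.7, 9.5, 5.7, 30.2, 84.9, 0.28, -0.25),
    "ND6":            (456, 40.6, 4.8, 4.2, 50.4, 91.0, -0.11, -0.09),
    "16S":            (1262, 45.9, 7.4, 4.4, 42.2, 88.1, -0.005, -0.3),
    "12S":            (726, 44.5, 6.9, 3.7, 44.9, 89.4, 0.04, -0.38),
    "rRNA_genes":     (1988, 45.4, 7.2, 4.2, 43.2, 88.6, 0.02, -0.27),
    "control_region": (588, 40.3, 2.4, 3.8, 53.5, 93.8, -0.14, 0.16),
}

#: Rows whose printed skews are arithmetically consistent with their own
#: printed percentages (several published cells, e.g. 16S and ND4, are not;
#: only the self-consistent rows are used in tests).
SELF_CONSISTENT_AT_SKEW_ROWS = ("ATP6", "COIII", "ND2", "CytB", "ND1")

#: Published codon tallies: total sense codons and the J-strand share.
CODON_TOTAL = 3573
CODON_J_STRAND = 2209
CODON_N_STRAND = 1364

#: Published control-region text length (the composition table prints 588 bp
#: while the text reports 578 bp; the text value is used by the generator).
CONTROL_REGION_LENGTH = 578
STEM_LOOP_SPAN = 42          # published: all biotype stem loops are 42 bp
CR_INVERTED_REPEAT_LEN = 144

# ---------------------------------------------------------------------------
# Repeat-region genotypes. RR-I sits between trnW and trnA and carries
# penta-nucleotide arrays; RR-II sits between trnI and COI and carries a
# 12-mer array. Counts are iterations; tuples are closed (lo, hi) ranges;
# lists of entries are interrupted (composite) arrays; None = motif absent.
# ---------------------------------------------------------------------------

RR1_MOTIFS = ("TAAAA", "AAATT", "TAAAT")
RR2_MOTIF = "ATTTATATTTAA"
RR2_VARIANT_MOTIF = "ATTTATATCTAA"   # GMB6 carries this variant in 2 copies

REPEAT_KEY_TABLE = {
    # biotype: {"rr1": {motif: count | (lo, hi) | [segments]}, "rr2": count,
    #           "rr2_variant_copies": int}
    "GMB1":      {"rr1": {"TAAAA": 25, "AAATT": 49}, "rr2": 5.4},
    "GMB2":      {"rr1": {"TAAAA": 11, "AAATT": 61}, "rr2": None},
    "GMB3":      {"rr1": {"TAAAA": [11, 5], "AAATT": [16, 29]}, "rr2": None},
    "GMB4":      {"rr1": {"TAAAA": 44, "TAAAT": (30, 33)}, "rr2": 3.4},
    "GMB4M":     {"rr1": {"TAAAA": 41, "AAATT": (28, 37)}, "rr2": 4.4},
    "GMB5":      {"rr1": {}, "rr2": None},
    "GMB6":      {"rr1": {"TAAAA": (5, 7), "AAATT": (52, 58)}, "rr2": 5.4,
                  "rr2_variant_copies": 2},
    "oryzivora": {"rr1": {}, "rr2": None},
    "fluvialis": {"rr1": {}, "rr2": None},
}

BIOTYPES = tuple(REPEAT_KEY_TABLE)
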
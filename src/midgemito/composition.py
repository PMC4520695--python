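"""Base composition, strand-skew and codon-usage (RSCU) statistics.

Strand asymmetry follows the standard formulas

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed on whatever sequence is handed in (whole genome, one strand's gene
set, or a single feature in coding sense). Percentages are reported to one
decimal and skews to two decimals, rounding half away from zero, matching the
precision of published mitogenome composition tables. ``N`` bases are
excluded from all denominators.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from Bio.Data import CodonTable

from .model import MitogenomeRecord, NucleotideSequence, extract_feature_sequence

INVERTEBRATE_MITO_TABLE_ID = 5


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (printed-table convention)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class CompositionSummary:
    """Composition of one sequence span (a composition-table row)."""

    length: int
    pctA: float
    pctC: float
    pctG: float
    pctT: float
    at_content: float
    at_skew: Optional[float]   # None when A+T == 0
    gc_skew: Optional[float]   # None when G+C == 0


def _as_str(seq) -> str:
    return str(seq).upper()


def base_composition(seq) -> CompositionSummary:
    """Composition summary of a sequence; percentages over non-N bases."""
    s = _as_str(seq)
    counts = Counter(s)
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    denom = a + c + g + t
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    pct = lambda x: round_half_away(100.0 * x / denom, 1)
    at = None if a + t == 0 else round_half_away((a - t) / (a + t), 2)
    gc = None if g + c == 0 else round_half_away((g - c) / (g + c), 2)
    return CompositionSummary(
        length=len(s),
        pctA=pct(a), pctC=pct(c), pctG=pct(g), pctT=pct(t),
        at_content=pct(a + t),
        at_skew=at, gc_skew=gc,
    )


def skew_from_percentages(pct_first: float, pct_second: float) -> Optional[float]:
    """Skew recomputed from two printed percentages.

    For AT skew pass (A%, T%); for GC skew pass (G%, C%). Returns None
    (undefined) when both percentages are zero.
    """
    denom = pct_first + pct_second
    if denom == 0:
        return None
    return round_half_away((pct_first - pct_second) / denom, 2)


def at_content_from_percentages(pctA: float, pctT: float) -> float:
    """A+T content as the sum of the printed A% and T%."""
    return round_half_away(pctA + pctT, 1)


# ---------------------------------------------------------------------------
# Per-record composition table
# ---------------------------------------------------------------------------

_GENE_CATEGORIES = ("PCG", "tRNA", "rRNA", "control_region")


def feature_composition_table(record: MitogenomeRecord) -> pd.DataFrame:
    """One composition row per annotated feature plus aggregate rows.

    Aggregates mirror the published table layout: whole genome, the J/N
    strand gene sets (concatenated coding-sense sequences of the genes each
    strand carries), all PCGs, all tRNAs, strand-wise tRNA sets and the rRNA
    pair. N-strand features contribute coding-sense sequence.
    """
    genes = [f for f in record.features if f.category in _GENE_CATEGORIES]
    if not genes:
        raise ValueError("record has no annotated features")

    seqs = {f.name: str(extract_feature_sequence(record, f)) for f in genes}

    def agg(names):
        return "".join(seqs[n] for n in names)

    by = lambda pred: [f.name for f in genes if pred(f)]
    rows = {
        "whole_genome": record.sequence.residues,
        "J_strand_genes": agg(by(lambda f: f.strand == "J" and f.category != "control_region")),
        "N_strand_genes": agg(by(lambda f: f.strand == "N")),
        "PCGs": agg(by(lambda f: f.category == "PCG")),
        "tRNAs": agg(by(lambda f: f.category == "tRNA")),
        "J_strand_tRNAs": agg(by(lambda f: f.category == "tRNA" and f.strand == "J")),
        "N_strand_tRNAs": agg(by(lambda f: f.category == "tRNA" and f.strand == "N")),
        "rRNA_genes": agg(by(lambda f: f.category == "rRNA")),
    }
    for f in genes:
        rows[f.name] = seqs[f.name]

    out = []
    for name, s in rows.items():
        if not s:
            continue
        summ = base_composition(s)
        out.append({
            "feature": name, "length": summ.length,
            "pctA": summ.pctA, "pctC": summ.pctC,
            "pctG": summ.pctG, "pctT": summ.pctT,
            "at_content": summ.at_content,
            "at_skew": summ.at_skew, "gc_skew": summ.gc_skew,
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Codon usage / RSCU (invertebrate mitochondrial code, table 5)
# ---------------------------------------------------------------------------

def _table5():
    return CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE_ID]


def sense_codons() -> list:
    """The 62 sense codons of the invertebrate mitochondrial code."""
    return sorted(_table5().forward_table)


def synonymous_families() -> dict:
    """amino acid -> list of synonymous codons (table 5)."""
    fams: dict = {}
    for codon, aa in _table5().forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: sorted(cods) for aa, cods in fams.items()}


@dataclass
class CodonUsageTable:
    counts: dict            # codon -> int, all 62 sense codons present
    rscu: dict              # codon -> float (0.0 for unused families)
    scope: str              # "J_strand" | "N_strand" | "all"
    total: int              # sum of counts


def rscu_from_counts(counts: dict) -> dict:
    """RSCU_c = count_c * family_size / family_total, per synonymous family."""
    rscu = {}
    for aa, codons in synonymous_families().items():
        family_total = sum(counts.get(c, 0) for c in codons)
        size = len(codons)
        for c in codons:
            rscu[c] = (counts.get(c, 0) * size / family_total) if family_total else 0.0
    return rscu


def codon_usage(record: MitogenomeRecord, scope: str = "all") -> CodonUsageTable:
    """Sense-codon counts and RSCU over the record's PCGs.

    Stop codons are excluded; a PCG whose length is not divisible by 3 has
    its trailing remainder dropped with a warning.
    """
    if scope not in ("all", "J_strand", "N_strand"):
        raise ValueError(f"unknown scope {scope!r}")
    stops = set(_table5().stop_codons)
    pcgs = [f for f in record.features if f.category == "PCG"]
    if scope != "all":
        pcgs = [f for f in pcgs if f.strand == ("J" if scope == "J_strand" else "N")]
    if not pcgs:
        raise ValueError("record has no protein-coding genes in scope")
    counts = {c: 0 for c in sense_codons()}
    total = 0
    for f in pcgs:
        s = str(extract_feature_sequence(record, f))
        if len(s) % 3:
            warnings.warn(
                f"{f.name}: length {len(s)} not divisible by 3; trailing "
                f"{len(s) % 3} nt dropped"
            )
            s = s[: len(s) - len(s) % 3]
        for i in range(0, len(s), 3):
            codon = s[i : i + 3]
            if codon in stops or codon not in counts:
                continue
            counts[codon] += 1
            total += 1
    return CodonUsageTable(
        counts=counts, rscu=rscu_from_counts(counts), scope=scope, total=total
    )


def strand_share_percent(strand_count: int, total: int) -> float:
    """Percentage of codons on one strand, to one decimal."""
    return round_half_away(100.0 * strand_count / total, 1)
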
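"""Data model and I/O for circular annotated insect mitogenomes.

Coordinate conventions used throughout the package:

* all coordinates are 0-based, half-open, on the linearized major (J) strand;
* the J strand is the strand carrying the majority of annotated genes;
* on circular records a feature's ``end`` may exceed the sequence length, in
  which case the span wraps the origin and is interpreted modulo length;
* GFF3 output converts to the standard 1-based inclusive convention with
  J/N mapped to ``+``/``-``.

Overlapping features are legal and never trimmed: real gall-midge gene
boundaries overlap by 2-31 nt.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALLOWED_RESIDUES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PCG_NAMES = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COI", "COII", "COIII", "ATP6", "ATP8", "CytB",
)
TRNA_NAMES = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG", "trnH",
    "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP", "trnS1",
    "trnS2", "trnT", "trnW", "trnY", "trnV",
)
RRNA_NAMES = ("16S", "12S")
REGION_NAMES = ("CR", "RR-I", "RR-II")

KNOWN_FEATURE_NAMES = frozenset(PCG_NAMES + TRNA_NAMES + RRNA_NAMES + REGION_NAMES)

CATEGORIES = ("PCG", "tRNA", "rRNA", "control_region", "repeat_region", "spacer")


class ParseError(ValueError):
    """Raised for malformed FASTA / feature-table input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideSequence:
    """An upper-case DNA string over {A,C,G,T,N}, optionally circular."""

    residues: str
    is_circular: bool = False

    def __post_init__(self):
        res = self.residues.upper()
        if not res:
            raise ValueError("empty sequence")
        bad = set(res) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(f"illegal residues: {sorted(bad)}")
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(reverse_complement(self.residues), self.is_circular)

    def span(self, start: int, end: int) -> str:
        """Subsequence [start, end); wraps the origin on circular sequences."""
        n = len(self.residues)
        if not (0 <= start < n) or end < start + 1:
            raise ValueError(f"bad span ({start}, {end}) for length {n}")
        if end <= n:
            return self.residues[start:end]
        if not self.is_circular:
            raise ValueError(
                f"span ({start}, {end}) exceeds linear sequence of length {n}"
            )
        if end - start > n:
            raise ValueError("span longer than circular sequence")
        return self.residues[start:] + self.residues[: end - n]


@dataclass
class GeneAnnotation:
    """One row of the feature table (the Table-1-style annotation model)."""

    name: str
    category: str
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    variable_arm_len: Optional[int] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in ("PCG", "tRNA", "rRNA", "control_region", "repeat_region"):
            if self.name not in KNOWN_FEATURE_NAMES:
                raise ValueError(f"unknown gene name {self.name!r}")
        if self.strand not in ("J", "N"):
            raise ValueError(f"strand must be J or N, got {self.strand!r}")
        if self.end - self.start < 1:
            raise ValueError(
                f"{self.name}: end - start must be >= 1 ({self.start}, {self.end})"
            )
        if (self.anticodon is not None) != (self.category == "tRNA"):
            raise ValueError(
                f"{self.name}: anticodon present iff category is tRNA"
            )
        for codon in (self.anticodon, self.start_codon, self.stop_codon):
            if codon is not None and (
                len(codon) != 3 or set(codon) - ALLOWED_RESIDUES
            ):
                raise ValueError(f"{self.name}: bad 3-mer {codon!r}")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class MitogenomeRecord:
    """A circular (or linearized) mitogenome with ordered feature annotations."""

    id: str
    sequence: NucleotideSequence
    features: list = field(default_factory=list)

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        seen = set()
        for f in self.features:
            if f.category in ("spacer", "repeat_region"):
                continue
            if f.name in seen:
                raise ValueError(f"duplicate feature name {f.name!r}")
            seen.add(f.name)

    def feature(self, name: str) -> GeneAnnotation:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def feature_names(self) -> list:
        return [f.name for f in self.features]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path, circular_default: bool = False) -> list:
    """Read a (multi-)FASTA file into records with empty feature lists.

    Circularity is taken from a ``circular`` token in the description line if
    present, else from *circular_default*. Residues are upper-cased; anything
    outside {A,C,G,T,N} is a parse error naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty FASTA file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">") or not line.strip():
            continue
        bad = set(line.strip().upper()) - ALLOWED_RESIDUES
        if bad:
            raise ParseError(
                f"{path}:{lineno}: illegal residue(s) {sorted(bad)}"
            )
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        tokens = rec.description.lower().split()
        circular = "circular" in tokens or circular_default
        records.append(
            MitogenomeRecord(
                id=rec.id,
                sequence=NucleotideSequence(str(rec.seq), is_circular=circular),
            )
        )
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(record: MitogenomeRecord, path) -> None:
    desc = "circular" if record.sequence.is_circular else ""
    rec = SeqRecord(Seq(record.sequence.residues), id=record.id, description=desc)
    SeqIO.write([rec], str(path), "fasta")


FEATURE_TABLE_COLUMNS = [
    "name", "category", "strand", "start", "end",
    "anticodon", "start_codon", "stop_codon", "variable_arm_len",
]


def _opt(value):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return None if s in ("-", "") else s


def read_feature_table(path) -> list:
    """Read the bespoke TSV feature-table dialect; ``-`` means absent."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(FEATURE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    annotations = []
    for idx, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise ParseError(f"{path}: row {idx}: non-integer coordinates") from exc
        var = _opt(row["variable_arm_len"])
        annotations.append(
            GeneAnnotation(
                name=row["name"],
                category=row["category"],
                strand=row["strand"],
                start=start,
                end=end,
                anticodon=_opt(row["anticodon"]),
                start_codon=_opt(row["start_codon"]),
                stop_codon=_opt(row["stop_codon"]),
                variable_arm_len=int(var) if var is not None else None,
            )
        )
    return annotations


def write_feature_table(record_or_features, path) -> None:
    features = getattr(record_or_features, "features", record_or_features)
    rows = []
    for f in features:
        rows.append({
            "name": f.name,
            "category": f.category,
            "strand": f.strand,
            "start": f.start,
            "end": f.end,
            "anticodon": f.anticodon or "-",
            "start_codon": f.start_codon or "-",
            "stop_codon": f.stop_codon or "-",
            "variable_arm_len": f.variable_arm_len if f.variable_arm_len is not None else "-",
        })
    pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


_GFF_TYPE = {
    "PCG": "gene",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "control_region": "D_loop",
    "repeat_region": "repeat_region",
    "spacer": "region",
}


def write_gff3(record: MitogenomeRecord, path) -> None:
    """Write features as GFF3 (1-based inclusive, J/N mapped to +/-)."""
    lines = ["##gff-version 3",
             f"##sequence-region {record.id} 1 {len(record.sequence)}"]
    for f in record.features:
        strand = "+" if f.strand == "J" else "-"
        attrs = [f"ID={f.name}", f"Name={f.name}", f"category={f.category}"]
        if f.anticodon:
            attrs.append(f"anticodon={f.anticodon}")
        lines.append("\t".join([
            record.id, "midgemito", _GFF_TYPE[f.category],
            str(f.start + 1), str(f.end), ".", strand, ".", ";".join(attrs),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sequence extraction and rotation
# ---------------------------------------------------------------------------

def extract_feature_sequence(
    record: MitogenomeRecord, annotation: GeneAnnotation
) -> NucleotideSequence:
    """Return a feature's coding-sense sequence.

    J-strand features are returned as annotated; N-strand features are
    reverse-complemented so the returned string reads in coding sense.
    Origin-spanning features on circular records concatenate tail + head.
    """
    raw = record.sequence.span(annotation.start, annotation.end)
    if annotation.strand == "N":
        raw = reverse_complement(raw)
    return NucleotideSequence(raw)


def linearize(record: MitogenomeRecord, origin_feature_name: str) -> MitogenomeRecord:
    """Rotate a circular record so the named feature starts at offset 0."""
    origin = record.feature(origin_feature_name)
    return rotate(record, origin.start)


def rotate(record: MitogenomeRecord, offset: int) -> MitogenomeRecord:
    """Rotate sequence and coordinates left by *offset* (circular records)."""
    n = len(record.sequence)
    offset %= n
    if offset == 0:
        return replace(record)
    if not record.sequence.is_circular:
        raise ValueError("cannot rotate a linear record")
    seq = record.sequence.residues
    new_seq = NucleotideSequence(seq[offset:] + seq[:offset], is_circular=True)
    new_feats = []
    for f in record.features:
        start = (f.start - offset) % n
        new_feats.append(replace(f, start=start, end=start + f.size))
    return MitogenomeRecord(id=record.id, sequence=new_seq, features=new_feats)
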
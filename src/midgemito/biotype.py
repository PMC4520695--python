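"""Repeat-based molecular typing of gall-midge biotypes.

The two intergenic repeat regions of the gall-midge mitogenome carry
biotype-diagnostic tandem arrays: RR-I (between trnW and trnA) holds
penta-nucleotide arrays (TAAAA / AAATT / TAAAT), RR-II (between trnI and COI)
a 12-mer array (ATTTATATTTAA). A genome is typed by extracting both loci,
profiling the arrays, and matching the profile against a key of expected
motif sets and iteration counts per biotype/species.

Motif presence/absence dominates the score - two of the published reference
genotypes (plus the GMB5 biotype) are distinguished purely by absence - and
iteration counts break ties among presence-compatible entries. Counts match
a key entry when they fall inside its (tolerance-widened) range; the default
15% relative tolerance reflects the copy-number heteroplasmy observed within
individuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import reference as ref
from .model import MitogenomeRecord
from .repeats import (
    CompositeArray,
    find_tandem_repeats,
    format_copies,
    group_interrupted,
    minimal_rotation,
)

RR1 = "RR-I"
RR2 = "RR-II"

_ANCHORS = {RR1: ("trnW", "trnA"), RR2: ("trnI", "COI")}


def extract_repeat_region(record: MitogenomeRecord, locus: str) -> str:
    """Subsequence strictly between the locus anchor genes (J-strand
    orientation); empty when the anchors are adjacent."""
    try:
        left_name, right_name = _ANCHORS[locus]
    except KeyError:
        raise ValueError(f"unknown locus {locus!r} (use 'RR-I' or 'RR-II')")
    left = record.feature(left_name)
    right = record.feature(right_name)
    if right.start == left.end:
        return ""
    if right.start > left.end:
        return record.sequence.span(left.end, right.start)
    if record.sequence.is_circular:
        return record.sequence.span(left.end, right.start + len(record.sequence))
    raise ValueError(f"anchors of {locus} out of order on a linear record")


@dataclass
class ArrayCall:
    """One detected (possibly interrupted) array at a repeat locus."""

    motif: str            # observed phase motif
    copies: float         # total copies across segments
    notation: str         # "25", "5.4" or "11+5"
    n_segments: int
    variant_copies: int = 0


@dataclass
class RepeatProfile:
    rr1: Dict[str, ArrayCall] = field(default_factory=dict)
    rr2: Optional[float] = None
    rr2_variant_copies: int = 0
    rr2_notation: Optional[str] = None
    cr_ta_copies: Optional[int] = None

    def is_empty(self) -> bool:
        return not self.rr1 and self.rr2 is None


def _calls_from_arrays(arrays: List[CompositeArray]) -> Dict[str, ArrayCall]:
    calls: Dict[str, ArrayCall] = {}
    for arr in arrays:
        call = ArrayCall(
            motif=arr.motif,
            copies=arr.total_copies,
            notation=arr.notation,
            n_segments=len(arr.segments),
            variant_copies=sum(seg.variant_copies for seg in arr.segments),
        )
        # keep the larger array if two share a phase motif
        old = calls.get(call.motif)
        if old is None or call.copies > old.copies:
            calls[call.motif] = call
    return calls


def build_repeat_profile(record: MitogenomeRecord, **detector_kwargs) -> RepeatProfile:
    """Profile both repeat loci (pentamer arrays at RR-I, 12-mers at RR-II)."""
    profile = RepeatProfile()
    rr1_seq = extract_repeat_region(record, RR1)
    if len(rr1_seq) >= 10:
        hits = [
            h for h in find_tandem_repeats(rr1_seq, 2, 20, **detector_kwargs)
            if h.period == 5
        ]
        profile.rr1 = _calls_from_arrays(group_interrupted(hits, rr1_seq))
    rr2_seq = extract_repeat_region(record, RR2)
    if len(rr2_seq) >= 24:
        hits = [
            h for h in find_tandem_repeats(rr2_seq, 2, 20, **detector_kwargs)
            if h.period == 12
        ]
        arrays = group_interrupted(hits, rr2_seq)
        if arrays:
            best = max(arrays, key=lambda a: a.total_copies)
            profile.rr2 = best.total_copies
            profile.rr2_notation = best.notation
            profile.rr2_variant_copies = sum(
                seg.variant_copies for seg in best.segments
            )
    try:
        cr = record.feature("CR")
    except KeyError:
        cr = None
    if cr is not None:
        from .control_region import count_cr_repeats
        from .model import extract_feature_sequence

        counts = count_cr_repeats(str(extract_feature_sequence(record, cr)))
        profile.cr_ta_copies = counts["ta_copies"]
    return profile


# ---------------------------------------------------------------------------
# Typing key
# ---------------------------------------------------------------------------

@dataclass
class MotifRange:
    lo: float
    hi: float
    segments: Optional[List[Tuple[float, float]]] = None   # interrupted arrays

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"malformed range {self.lo}-{self.hi}")

    def contains(self, value: float, tol: float) -> bool:
        return self.lo * (1 - tol) <= value <= self.hi * (1 + tol)


@dataclass
class KeyEntry:
    rr1: Dict[str, MotifRange]
    rr2: Optional[MotifRange]


@dataclass
class BiotypeKey:
    entries: Dict[str, KeyEntry]
    provenance: str = "published gall-midge repeat tables"

    def __post_init__(self):
        if len(self.entries) != len(set(self.entries)):
            raise ValueError("duplicate biotype names in key")


def _to_range(value) -> Optional[MotifRange]:
    if value is None:
        return None
    if isinstance(value, tuple):
        return MotifRange(float(value[0]), float(value[1]))
    if isinstance(value, list):       # composite: total count, segments kept
        total = float(sum(value))
        return MotifRange(total, total,
                          segments=[(float(v), float(v)) for v in value])
    return MotifRange(float(value), float(value))


def default_biotype_key() -> BiotypeKey:
    entries = {}
    for name, row in ref.REPEAT_KEY_TABLE.items():
        entries[name] = KeyEntry(
            rr1={m: _to_range(v) for m, v in row["rr1"].items()},
            rr2=_to_range(row["rr2"]),
        )
    return BiotypeKey(entries=entries)


def load_biotype_key(path: Optional[str] = None) -> BiotypeKey:
    """Load a JSON key ({name: {"rr1": {motif: [lo, hi] | {"segments": ...}},
    "rr2": [lo, hi] | null}}) or the shipped default."""
    if path is None:
        return default_biotype_key()
    with open(path) as fh:
        raw = json.load(fh)
    entries = {}
    for name, row in raw.items():
        rr1 = {}
        for motif, v in row.get("rr1", {}).items():
            if isinstance(v, dict):
                segs = [(float(a), float(b)) for a, b in v["segments"]]
                total_lo = sum(a for a, _ in segs)
                total_hi = sum(b for _, b in segs)
                rr1[motif.upper()] = MotifRange(total_lo, total_hi, segments=segs)
            else:
                rr1[motif.upper()] = MotifRange(float(v[0]), float(v[1]))
        rr2 = row.get("rr2")
        entries[name] = KeyEntry(
            rr1=rr1,
            rr2=MotifRange(float(rr2[0]), float(rr2[1])) if rr2 else None,
        )
    return BiotypeKey(entries=entries, provenance=str(path))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class TypingResult:
    best: List[str]
    scores: Dict[str, Tuple[float, float]]
    ambiguous: bool
    evidence: Dict[str, List[str]]


def _motif_matches(profile_motif: str, key_motif: str) -> float:
    """1.0 for an exact phase match, 0.5 for a rotation of the key motif."""
    if profile_motif == key_motif:
        return 1.0
    if minimal_rotation(profile_motif) == minimal_rotation(key_motif):
        return 0.5
    return 0.0


def classify_biotype(
    profile: RepeatProfile,
    key: Optional[BiotypeKey] = None,
    count_tolerance: float = 0.15,
) -> TypingResult:
    """Match a repeat profile against the key.

    Score is lexicographic: motif presence/absence agreement first (RR-I
    motif set plus RR-II presence), then the fraction of expected counts
    matched within tolerance. Ties yield an ambiguous result set.
    """
    key = key or default_biotype_key()
    if not key.entries:
        raise ValueError("empty biotype key")
    scores: Dict[str, Tuple[float, float]] = {}
    evidence: Dict[str, List[str]] = {}
    for name, entry in key.entries.items():
        notes = []
        presence = 0.0
        count_checks: List[bool] = []
        matched_profile_motifs = set()
        for key_motif, rng in entry.rr1.items():
            match = max(
                ((pm, _motif_matches(pm, key_motif)) for pm in profile.rr1),
                key=lambda x: x[1],
                default=(None, 0.0),
            )
            pm, strength = match
            if strength > 0:
                presence += strength
                matched_profile_motifs.add(pm)
                ok = rng.contains(profile.rr1[pm].copies, count_tolerance)
                count_checks.append(ok)
                notes.append(
                    f"RR-I {key_motif}: observed {profile.rr1[pm].notation} "
                    f"({'in' if ok else 'out of'} range {rng.lo}-{rng.hi})"
                )
            else:
                presence -= 1.0
                notes.append(f"RR-I {key_motif}: expected but absent")
        for pm in profile.rr1:
            if pm not in matched_profile_motifs:
                presence -= 1.0
                notes.append(f"RR-I {pm}: observed but not expected")
        if (profile.rr2 is not None) == (entry.rr2 is not None):
            presence += 1.0
            if profile.rr2 is not None:
                ok = entry.rr2.contains(profile.rr2, count_tolerance)
                count_checks.append(ok)
                notes.append(
                    f"RR-II: observed {format_copies(profile.rr2)} copies "
                    f"({'in' if ok else 'out of'} range {entry.rr2.lo}-{entry.rr2.hi})"
                )
            else:
                notes.append("RR-II: absent as expected")
        else:
            presence -= 1.0
            notes.append("RR-II: presence/absence mismatch")
        count_score = (
            sum(count_checks) / len(count_checks) if count_checks else 1.0
        )
        scores[name] = (presence, count_score)
        evidence[name] = notes
    best_score = max(scores.values())
    best = sorted(n for n, s in scores.items() if s == best_score)
    return TypingResult(
        best=best,
        scores=scores,
        ambiguous=len(best) > 1,
        evidence=evidence,
    )


def type_record(
    record: MitogenomeRecord,
    key: Optional[BiotypeKey] = None,
    count_tolerance: float = 0.15,
) -> TypingResult:
    """Convenience: profile a genome and classify it in one call."""
    return classify_biotype(build_repeat_profile(record), key, count_tolerance)
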
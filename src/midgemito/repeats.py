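"""Tandem-repeat and inverted-repeat detection.

The tandem detector is a period-wise scan over the self-match profile
``m_p[i] = (s[i] == s[i-p])``: maximal runs of matches are perfect arrays;
with a mismatch tolerance, runs are bridged across short mismatch gaps so
that arrays carrying point variants (e.g. a 12-mer array in which two copies
differ by one substitution) are still reported as a single hit. Copy numbers
are fractional (span / period) and reported to one decimal, reproducing the
"5.4 iterations"-style notation of repeat-typing tables.

A hit's ``motif`` is canonicalized to the lexicographically minimal rotation;
the rotation actually observed at the array start is kept as ``phase`` so
that motifs that are rotations of one another (the published pentamer motifs
AAATT and TAAAT are) remain distinguishable when the array boundary is known.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .model import reverse_complement


def minimal_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def primitive_root(motif: str) -> str:
    """Smallest unit u with motif == u * k (the motif itself if primitive)."""
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return motif[:d]
    return motif


def format_copies(copies: float) -> str:
    r = round(copies, 1)
    return str(int(r)) if r == int(r) else f"{r:.1f}"


@dataclass
class TandemRepeatHit:
    motif: str            # canonical (lexicographically minimal rotation)
    phase: str            # motif as observed at the array start
    period: int
    start: int            # 0-based half-open span
    end: int
    copies: float         # span / period, 1 decimal
    identity: float       # fraction of span matching a perfect array
    variant_copies: int   # full copies differing from the consensus motif

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)


@dataclass
class CompositeArray:
    """Same-motif arrays separated by short non-repetitive spacers."""

    motif: str
    segments: List[TandemRepeatHit]
    notation: str         # e.g. "11+5" for an interrupted array, "25" for one

    @property
    def total_copies(self) -> float:
        return round(sum(seg.copies for seg in self.segments), 1)

    @property
    def start(self) -> int:
        return self.segments[0].start

    @property
    def end(self) -> int:
        return self.segments[-1].end


def _true_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive indices."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def _merge_runs(
    runs: List[Tuple[int, int]], period: int, max_mismatch_frac: float
) -> List[Tuple[int, int, int]]:
    """Bridge runs across mismatch gaps; returns (first, last, mismatches).

    A gap may be bridged when it is shorter than one period's mismatch budget
    (at least 1) and the merged stretch keeps its overall mismatch fraction
    within tolerance. Longer gaps - e.g. the junction between two arrays of
    different motifs, where most of one period mismatches - stay unbridged.
    """
    cap = max(1, int(max_mismatch_frac * period))
    merged = []
    cur_first, cur_last = runs[0]
    mism = 0
    for first, last in runs[1:]:
        gap = first - cur_last - 1
        new_mism = mism + gap
        length = last - cur_first + 1
        if gap <= cap and max_mismatch_frac > 0 and new_mism / length <= max_mismatch_frac:
            cur_last, mism = last, new_mism
        else:
            merged.append((cur_first, cur_last, mism))
            cur_first, cur_last, mism = first, last, 0
    merged.append((cur_first, cur_last, mism))
    return merged


def _consensus_motif(s: str, start: int, end: int, period: int) -> str:
    cols = []
    for j in range(period):
        cols.append(Counter(s[start + j : end : period]).most_common(1)[0][0])
    return "".join(cols)


def find_tandem_repeats(
    seq,
    min_period: int = 2,
    max_period: int = 20,
    min_copies: float = 3,
    max_mismatch_frac: float = 0.1,
) -> List[TandemRepeatHit]:
    """Detect tandem arrays of period ``min_period..max_period``.

    Returns non-nested hits sorted by start. Hits whose consensus motif is a
    power of a shorter unit are suppressed (the primitive period emits its
    own hit), so a poly-A tract yields nothing at ``min_period=2``.
    """
    s = str(seq).upper()
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    if n < 2 * min_period:
        return []
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    candidates: List[TandemRepeatHit] = []
    for p in range(min_period, max_period + 1):
        if n < 2 * p:
            break
        mask = arr[p:] == arr[:-p]
        runs = _true_runs(mask)
        if not runs:
            continue
        # shift run indices from mask coordinates to sequence coordinates
        runs = [(a + p, b + p) for a, b in runs]
        for first, last, _ in _merge_runs(runs, p, max_mismatch_frac):
            start, end = first - p, last + 1
            copies = (end - start) / p
            if copies < min_copies:
                continue
            motif = _consensus_motif(s, start, end, p)
            root = primitive_root(motif)
            if len(root) < max(min_period, p):
                continue
            tiled = (motif * (((end - start) // p) + 1))[: end - start]
            window = s[start:end]
            matches = sum(a == b for a, b in zip(window, tiled))
            identity = matches / (end - start)
            if identity < 1.0 - max_mismatch_frac:
                continue
            variant = sum(
                1
                for k in range((end - start) // p)
                if window[k * p : (k + 1) * p] != motif
            )
            candidates.append(
                TandemRepeatHit(
                    motif=minimal_rotation(motif),
                    phase=motif,
                    period=p,
                    start=start,
                    end=end,
                    copies=round(copies, 1),
                    identity=identity,
                    variant_copies=variant,
                )
            )
    # non-nesting: prefer higher copy number, then smaller period
    candidates.sort(key=lambda h: (-h.copies, h.period, h.start))
    accepted: List[TandemRepeatHit] = []
    for h in candidates:
        if any(g.start <= h.start and h.end <= g.end for g in accepted):
            continue
        accepted.append(h)
    accepted.sort(key=lambda h: (h.start, h.period))
    return accepted


def group_interrupted(
    hits: List[TandemRepeatHit], seq=None, max_gap: int = 200
) -> List[CompositeArray]:
    """Merge same-motif hits within ``max_gap`` into composite arrays.

    A composite of two segments of 11 and 5 copies gets notation "11+5";
    a lone hit is a singleton array with notation "25"-style.
    """
    by_motif: dict = {}
    for h in sorted(hits, key=lambda h: h.start):
        by_motif.setdefault((h.motif, h.period), []).append(h)
    arrays: List[CompositeArray] = []
    for (_motif, _period), group in by_motif.items():
        chain = [group[0]]
        for h in group[1:]:
            if h.start - chain[-1].end <= max_gap:
                chain.append(h)
            else:
                arrays.append(_composite(chain))
                chain = [h]
        arrays.append(_composite(chain))
    arrays.sort(key=lambda a: a.start)
    return arrays


def _composite(segments: List[TandemRepeatHit]) -> CompositeArray:
    return CompositeArray(
        motif=segments[0].phase,
        segments=segments,
        notation="+".join(format_copies(seg.copies) for seg in segments),
    )


def count_variant_copies(hit: TandemRepeatHit, seq, variant_motif: str) -> int:
    """Number of full copies in the hit equal to ``variant_motif``."""
    if len(variant_motif) != hit.period:
        raise ValueError("variant motif length must equal the hit period")
    s = str(seq).upper()
    variant = variant_motif.upper()
    return sum(
        1
        for k in range((hit.end - hit.start) // hit.period)
        if s[hit.start + k * hit.period : hit.start + (k + 1) * hit.period] == variant
    )


# ---------------------------------------------------------------------------
# Inverted repeats
# ---------------------------------------------------------------------------

def find_inverted_repeats(
    seq,
    min_len: int = 30,
    max_spacer: int = 600,
    max_mismatch_frac: float = 0.1,
    seed_len: int = 12,
) -> List[Tuple[Tuple[int, int], Tuple[int, int]]]:
    """Arm pairs where the downstream arm matches the reverse complement of
    the upstream arm. Returns ((a1, b1), (a2, b2)) span pairs (0-based
    half-open, equal arm lengths, spacer b1..a2 possibly zero - the hairpin
    limit), ranked by arm length.
    """
    s = str(seq).upper()
    n = len(s)
    k = min(seed_len, min_len)
    if n < 2 * k:
        return []
    kmers: dict = {}
    for i in range(n - k + 1):
        kmers.setdefault(s[i : i + k], []).append(i)
    pairs = set()
    for i in range(n - k + 1):
        rc = reverse_complement(s[i : i + k])
        for j in kmers.get(rc, ()):
            if j <= i:
                continue
            pairs.add(_extend_ir(s, i, i + k, j, j + k, max_mismatch_frac))
    out = []
    for a1, b1, a2, b2 in pairs:
        arm = b1 - a1
        if arm >= min_len and b1 <= a2 and (a2 - b1) <= max_spacer:
            out.append(((a1, b1), (a2, b2)))
    # drop pairs fully contained in a larger one
    out.sort(key=lambda pr: -(pr[0][1] - pr[0][0]))
    kept = []
    for (a1, b1), (a2, b2) in out:
        if any(
            c1 <= a1 and b1 <= d1 and c2 <= a2 and b2 <= d2
            for (c1, d1), (c2, d2) in kept
        ):
            continue
        kept.append(((a1, b1), (a2, b2)))
    return kept


def _complementary(x: str, y: str) -> bool:
    return y == reverse_complement(x)


def _extend_ir(s, a1, b1, a2, b2, frac):
    """Greedy maximal extension of a seeded arm pair with a mismatch budget."""
    n = len(s)
    mismatches = 0

    def budget(arm_len):
        return int(frac * arm_len)

    progress = True
    while progress:
        progress = False
        arm = b1 - a1
        # outward: position a1-1 pairs with b2
        if a1 > 0 and b2 < n:
            ok = _complementary(s[a1 - 1], s[b2])
            if ok or mismatches + 1 <= budget(arm + 1):
                a1 -= 1
                b2 += 1
                mismatches += 0 if ok else 1
                progress = True
                continue
        # inward: position b1 pairs with a2-1 (keep spacer >= 0)
        if a2 - b1 >= 2:
            ok = _complementary(s[b1], s[a2 - 1])
            if ok or mismatches + 1 <= budget(arm + 1):
                b1 += 1
                a2 -= 1
                mismatches += 0 if ok else 1
                progress = True
    # trim mismatching extremities
    while b1 > a1 and not _complementary(s[a1], s[b2 - 1]):
        a1 += 1
        b2 -= 1
    while b1 > a1 and not _complementary(s[b1 - 1], s[a2]):
        b1 -= 1
        a2 += 1
    return (a1, b1, a2, b2)
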
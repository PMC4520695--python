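"""Control-region (D-loop) structural element scanning.

Arthropod mitochondrial control regions carry five conserved elements, in
conserved order on one strand: a poly-T stretch, a [TA(A)]n tract, a stem-loop
hairpin flanked by a 5' "TATA" and a 3' "G(A)nT" consensus, and a downstream
G+A-rich domain. This module locates them with explicit pattern / pairing
rules - there is no thermodynamic folding; the hairpin search is a
complement-match search over arm/loop partitions (Watson-Crick plus optional
G*T wobble).

Decision rules (configurable via :class:`CRScanParams`):

* poly-T: >= 8 T's allowing one single-base interruption;
* TA tract: >= 4 tandem TA copies allowing single-A insertions;
* TATA: literal match within 30 bp upstream of the stem (closest one wins);
* G(A)nT: literal G, then 2-12 A, then T, downstream of the stem;
* G+A-rich: first downstream region whose 30-nt windows have purine
  fraction >= 0.8, trimmed to its outermost purines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .model import reverse_complement
from .repeats import find_tandem_repeats

Span = Tuple[int, int]

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "T"), ("T", "G")}


def _pairs(x: str, y: str, allow_gu: bool = True) -> bool:
    return (x, y) in _WC or (allow_gu and (x, y) in _GU)


@dataclass
class StemLoop:
    span: Span
    stem_len: int
    loop_len: int
    mismatches: int

    @property
    def paired(self) -> int:
        return self.stem_len - self.mismatches


@dataclass
class CRScanParams:
    min_length: int = 100
    max_length: int = 2000
    poly_t_min: int = 8          # T count, one interruption allowed
    ta_min_copies: int = 4
    stem_min: int = 10
    stem_loop_range: Tuple[int, int] = (3, 30)
    stem_max_mismatch: int = 0   # scan-level default: exact stems only
    allow_gu: bool = True
    tata_window: int = 30
    gant_window: int = 40
    ga_window: int = 30
    ga_purine_frac: float = 0.8


@dataclass
class ControlRegionAnnotation:
    poly_t: Optional[Span]
    ta_tract: Optional[Span]
    ta_copies: Optional[int]
    stem_loop: Optional[StemLoop]
    consensus_5p: Optional[Span]
    consensus_3p: Optional[Span]
    ga_rich: Optional[Span]
    inverted_repeat: Optional[Tuple[Span, Span]]
    order_conserved: bool
    strand: str = "+"

    def found_elements(self) -> List[str]:
        names = []
        for name in ("poly_t", "ta_tract", "stem_loop", "consensus_5p",
                     "consensus_3p", "ga_rich"):
            if getattr(self, name) is not None:
                names.append(name)
        return names


# ---------------------------------------------------------------------------
# Hairpin search
# ---------------------------------------------------------------------------

def hairpin_search(
    seq,
    min_stem: int = 8,
    loop_range: Tuple[int, int] = (3, 30),
    max_mismatch: int = 2,
    allow_gu: bool = True,
) -> List[StemLoop]:
    """Stem-loop candidates where a prefix arm pairs with the reverse
    complement of a suffix arm around a loop, ranked by paired positions,
    then fewer mismatches, then stem length.

    The scan walks anti-diagonals of the pairing matrix: every pair of a
    hairpin whose arms close at positions (x, y) satisfies x + y = const.
    """
    s = str(seq).upper()
    n = len(s)
    loop_min, loop_max = loop_range
    if n < 2 * min_stem + loop_min:
        return []
    candidates: List[StemLoop] = []
    for diag in range(2 * min_stem + loop_min - 1, 2 * n - 2):
        # pairs (x, y = diag - x); innermost allowed x keeps loop >= loop_min
        x_hi = (diag - loop_min - 1) // 2
        x_lo_loopmax = (diag - loop_max - 1 + 1) // 2   # loop <= loop_max
        if x_hi < 0:
            continue
        x_hi = min(x_hi, n - 1)
        paired = []
        for x in range(0, x_hi + 1):
            y = diag - x
            if y >= n or y <= x:
                paired.append(False)
            else:
                paired.append(_pairs(s[x], s[y], allow_gu))
        # maximal paired runs, bridging <= max_mismatch single gaps
        x = 0
        while x <= x_hi:
            if not paired[x]:
                x += 1
                continue
            end = x
            mismatches = 0
            j = x + 1
            pending_gap = 0
            while j <= x_hi:
                if paired[j]:
                    if mismatches + pending_gap > max_mismatch:
                        break
                    mismatches += pending_gap
                    pending_gap = 0
                    end = j
                else:
                    pending_gap += 1
                j += 1
            stem_len = end - x + 1
            loop = diag - 2 * end - 1
            if (
                stem_len >= min_stem
                and end >= x_lo_loopmax
                and loop_min <= loop <= loop_max
            ):
                candidates.append(
                    StemLoop(
                        span=(x, diag - x + 1),
                        stem_len=stem_len,
                        loop_len=loop,
                        mismatches=mismatches,
                    )
                )
            x = max(j, x + 1)
    candidates.sort(key=lambda c: (-c.paired, c.mismatches, -c.stem_len, c.span))
    return candidates


# ---------------------------------------------------------------------------
# Element finders
# ---------------------------------------------------------------------------

def _find_poly_t(s: str, min_t: int) -> Optional[Span]:
    runs = [(m.start(), m.end()) for m in re.finditer(r"T+", s)]
    best: Optional[Tuple[int, Span]] = None
    candidates: List[Tuple[int, Span]] = [(b - a, (a, b)) for a, b in runs]
    for (a1, b1), (a2, b2) in zip(runs, runs[1:]):
        if a2 - b1 == 1:  # single non-T interruption
            candidates.append(((b1 - a1) + (b2 - a2), (a1, b2)))
    for t_count, span in candidates:
        if t_count >= min_t and (best is None or t_count > best[0]):
            best = (t_count, span)
    return best[1] if best else None


_TA_UNIT = re.compile(r"(?:TAA?)+")


def _count_ta_units(segment: str) -> int:
    return len(re.findall(r"TAA?", segment))


def find_ta_tract(s: str, min_copies: int) -> Tuple[Optional[Span], Optional[int]]:
    best: Optional[Tuple[int, Span]] = None
    for m in _TA_UNIT.finditer(s):
        units = _count_ta_units(m.group())
        if units >= min_copies and (
            best is None or (m.end() - m.start()) > (best[1][1] - best[1][0])
        ):
            best = (units, (m.start(), m.end()))
    if best is None:
        return None, None
    return best[1], best[0]


def _find_tata(s: str, stem_start: int, window: int) -> Optional[Span]:
    lo = max(0, stem_start - window)
    region = s[lo:stem_start]
    pos = region.rfind("TATA")
    return (lo + pos, lo + pos + 4) if pos >= 0 else None


_GANT = re.compile(r"GA{2,12}T")


def _find_gant(s: str, stem_end: int, window: int) -> Optional[Span]:
    m = _GANT.search(s, stem_end, min(len(s), stem_end + window))
    return (m.start(), m.end()) if m else None


def _find_ga_rich(s: str, start: int, window: int, frac: float) -> Optional[Span]:
    n = len(s)
    purine = [c in "AG" for c in s]
    qual = []
    for x in range(start, n - window + 1):
        if sum(purine[x : x + window]) >= frac * window:
            qual.append(x)
    if not qual:
        return None
    # first contiguous cluster of qualifying windows
    first = qual[0]
    last = first
    for x in qual[1:]:
        if x <= last + 1:
            last = x
        else:
            break
    lo, hi = first, last + window
    while lo < hi and not purine[lo]:
        lo += 1
    while hi > lo and not purine[hi - 1]:
        hi -= 1
    return (lo, hi) if hi > lo else None


def mirror_span(span: Span, length: int) -> Span:
    a, b = span
    return (length - b, length - a)


def scan_control_region(
    seq, params: Optional[CRScanParams] = None, orientation: str = "+"
) -> ControlRegionAnnotation:
    """Locate the five conserved elements (and any long inverted repeat).

    ``orientation`` may be "+", "-" (scan the reverse complement; reported
    spans are in the scanned orientation's coordinates) or "auto" (scan both,
    keep the orientation finding more elements; "+" wins ties).
    """
    params = params or CRScanParams()
    s = str(seq).upper()
    if not (params.min_length <= len(s) <= params.max_length):
        raise ValueError(
            f"control region length {len(s)} outside "
            f"[{params.min_length}, {params.max_length}]"
        )
    if orientation == "auto":
        fwd = scan_control_region(s, params, "+")
        rev = scan_control_region(s, params, "-")
        return fwd if len(fwd.found_elements()) >= len(rev.found_elements()) else rev
    if orientation == "-":
        ann = scan_control_region(reverse_complement(s), params, "+")
        ann.strand = "-"
        return ann

    poly_t = _find_poly_t(s, params.poly_t_min)
    ta_span, ta_copies = find_ta_tract(s, params.ta_min_copies)

    hairpins = hairpin_search(
        s,
        min_stem=params.stem_min,
        loop_range=params.stem_loop_range,
        max_mismatch=params.stem_max_mismatch,
        allow_gu=params.allow_gu,
    )
    stem = None
    for cand in hairpins[:10]:
        if _find_tata(s, cand.span[0], params.tata_window):
            stem = cand
            break
    if stem is None and hairpins:
        stem = hairpins[0]

    tata = gant = ga = None
    if stem is not None:
        tata = _find_tata(s, stem.span[0], params.tata_window)
        gant = _find_gant(s, stem.span[1], params.gant_window)
        ga = _find_ga_rich(
            s, stem.span[1], params.ga_window, params.ga_purine_frac
        )

    from .repeats import find_inverted_repeats

    irs = find_inverted_repeats(s, min_len=30, max_spacer=len(s))
    inverted_repeat = irs[0] if irs else None

    starts = []
    for el in (poly_t, ta_span,
               tata, stem.span if stem else None, gant, ga):
        if el is not None:
            starts.append(el[0])
    order_conserved = starts == sorted(starts) and len(starts) >= 2

    return ControlRegionAnnotation(
        poly_t=poly_t,
        ta_tract=ta_span,
        ta_copies=ta_copies,
        stem_loop=stem,
        consensus_5p=tata,
        consensus_3p=gant,
        ga_rich=ga,
        inverted_repeat=inverted_repeat,
        order_conserved=order_conserved,
        strand="+",
    )


def count_cr_repeats(seq) -> dict:
    """TA copy number and any long (50-150 bp unit) repeat in a CR."""
    s = str(seq).upper()
    out = {"ta_copies": None, "long_repeat": None}
    ta_hits = [
        h for h in find_tandem_repeats(s, 2, 2, min_copies=4)
        if set(h.phase) == {"A", "T"}
    ]
    if ta_hits:
        best = max(ta_hits, key=lambda h: h.copies)
        out["ta_copies"] = int(best.copies)
    if len(s) >= 100:
        long_hits = find_tandem_repeats(
            s, min_period=50, max_period=150, min_copies=2
        )
        if long_hits:
            best = max(long_hits, key=lambda h: h.end - h.start)
            out["long_repeat"] = {"unit_len": best.period, "copies": best.copies}
    return out
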
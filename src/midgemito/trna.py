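"""Cloverleaf secondary-structure assessment for mitochondrial tRNAs.

Gall-midge mitochondrial tRNAs are frequently truncated: D-arms or T-arms may
be missing, the T-arm plus variable arm can collapse into a single "TV" loop,
and variable arms range from absent to long five-arm "star-like" forms. This
module folds an annotated tRNA sequence by exhaustive search over arm
boundary placements within canonical size windows, scoring total paired
positions (Watson-Crick and G*T wobble score equally), and classifies the
truncations. It does not discover tRNA genes and uses no thermodynamics.

Arm windows searched (bp): acceptor stem 6-8 (canonical 7), D-stem 3-4 with
loop 4-9, anticodon stem 4-5 with a 7-nt loop (anticodon at its centre),
variable region 0-23, T-stem 3-5 with loop 3-9. An arm is called absent when
no placement achieves >= 3 paired positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}

MIN_LEN, MAX_LEN = 50, 110
MIN_STEM_PAIRS = 3          # an arm exists if its stem pairs >= this
ARM_PENALTY = 2.0           # score cost of declaring a D- or T-arm present;
                            # a chance 3-pair "arm" then cannot outbid the
                            # parsimonious layout in A+T-rich sequence

# label vocabulary for classify_truncation
D_ARM_MISSING = "D-arm missing"
T_ARM_MISSING = "T-arm missing/TV-loop"
SHORT_T_ARM = "short T-arm"
SHORT_VARIABLE_ARM = "short variable arm"
LONG_VARIABLE_ARM = "long variable arm"
NO_VARIABLE_ARM = "no variable arm"

LONG_VARIABLE_MIN = 15      # the "star-like" class
SHORT_VARIABLE_MAX = 2
SHORT_T_ARM_MAX = 8         # stem + loop length of a markedly reduced T-arm


@dataclass
class Arm:
    present: bool
    stem_len: int = 0
    loop_len: int = 0
    pairs: int = 0


@dataclass
class TrnaStructure:
    acceptor_stem: int                 # paired positions in the acceptor stem
    d_arm: Arm
    anticodon_arm: Arm
    anticodon: Optional[str]
    t_arm: Arm
    tv_loop: bool
    variable_arm_len: int
    score: int


def _stem_pairs(s: str, start: int, stem: int, loop: int) -> int:
    """Paired positions of a hairpin arm: s[start:start+stem] against the
    complement of s[start+stem+loop : start+2*stem+loop] read backwards."""
    total = 0
    for k in range(stem):
        x = s[start + k]
        y = s[start + 2 * stem + loop - 1 - k]
        if (x, y) in _PAIRS:
            total += 1
    return total


def _acceptor_pairs(s: str, a: int, t: int) -> int:
    n = len(s)
    return sum(
        1 for k in range(a) if (s[k], s[n - t - 1 - k]) in _PAIRS
    )


def fold_cloverleaf(
    seq,
    anticodon_hint: Optional[str] = None,
    max_arm_mismatch: int = 0,
) -> TrnaStructure:
    """Best cloverleaf placement by exhaustive constrained search.

    A D-, anticodon- or T-stem placement is only admissible when it pairs
    throughout (up to ``max_arm_mismatch`` unpaired positions) - stems are
    helices, and demanding contiguous pairing is what keeps chance pairs in
    A+T-rich sequence from faking an arm. Ties are broken toward canonical
    arm sizes (acceptor 7, D 3-4 with 2/1 spacers, anticodon stem 5, T stem
    4-5). Raises if no placement yields an admissible anticodon arm.
    """
    s = str(seq).upper()
    n = len(s)
    if not (MIN_LEN <= n <= MAX_LEN):
        raise ValueError(f"tRNA length {n} outside [{MIN_LEN}, {MAX_LEN}]")
    hint = anticodon_hint.upper() if anticodon_hint else None

    best = None
    best_key = None
    cs_cache = {}
    for t in (0, 1):                       # unpaired 3' overhang
        for a in (7, 6, 8):                # acceptor stem length
            acc = _acceptor_pairs(s, a, t)
            interior_end = n - t - a
            # D-arm placements: (d_pairs, d_stem, d_loop, end_of_d_region)
            d_options: List[Tuple[int, int, int, int]] = []
            for connector in range(4, 13):     # D-arm absent
                if a + connector <= interior_end:
                    d_options.append((0, 0, connector, a + connector))
            for sp0 in (2, 1, 3):
                for ds in (4, 3):
                    for dl in range(4, 10):
                        d0 = a + sp0
                        d_end = d0 + 2 * ds + dl
                        if d_end > interior_end:
                            continue
                        dp = _stem_pairs(s, d0, ds, dl)
                        if dp >= MIN_STEM_PAIRS and dp >= ds - max_arm_mismatch:
                            d_options.append((dp, ds, dl, d_end))
            for dp, ds, dl, d_end in d_options:
                for sp1 in (1, 0, 2):
                    c0 = d_end + sp1
                    for cs in (5, 4):
                        cl = 7
                        c_end = c0 + 2 * cs + cl
                        if c_end > interior_end:
                            continue
                        key = (c0, cs)
                        cp = cs_cache.get(key)
                        if cp is None:
                            cp = _stem_pairs(s, c0, cs, cl)
                            cs_cache[key] = cp
                        if cp < MIN_STEM_PAIRS or cp < cs - max_arm_mismatch:
                            continue
                        anticodon = s[c0 + cs + 2 : c0 + cs + 5]
                        rest = interior_end - c_end
                        # T-arm absent: the whole rest is a single (TV) loop
                        t_options = [(0, 0, rest, 0)] if 0 <= rest <= 25 else []
                        for ts in (4, 5, 3):
                            for tl in range(3, 10):
                                v = rest - (2 * ts + tl)
                                if not (0 <= v <= 23):
                                    continue
                                tp = _stem_pairs(s, c_end + v, ts, tl)
                                if tp >= MIN_STEM_PAIRS and tp >= ts - max_arm_mismatch:
                                    t_options.append((tp, ts, tl, v))
                        for tp, ts, tl, v in t_options:
                            score = acc + dp + cp + tp
                            penalty = ARM_PENALTY * ((ds > 0) + (ts > 0))
                            bonus = 0.5 if (hint and anticodon == hint) else 0.0
                            bonus -= penalty
                            canon = (
                                -(a == 7),
                                -(ds in (3, 4)),
                                -(cs == 5),
                                -(ts in (4, 5)),
                                abs(v - 4),
                                t,
                            )
                            cand_key = (-(score + bonus), canon)
                            if best_key is None or cand_key < best_key:
                                best_key = cand_key
                                best = (t, a, acc, dp, ds, dl, cp, cs,
                                        anticodon, tp, ts, tl, v, score)
    if best is None:
        raise ValueError("no cloverleaf configuration found")
    (t, a, acc, dp, ds, dl, cp, cs, anticodon, tp, ts, tl, v, score) = best
    d_present = ds > 0
    t_present = ts > 0
    return TrnaStructure(
        acceptor_stem=acc,
        d_arm=Arm(present=d_present, stem_len=ds, loop_len=dl, pairs=dp),
        anticodon_arm=Arm(present=True, stem_len=cs, loop_len=7, pairs=cp),
        anticodon=anticodon,
        t_arm=Arm(present=t_present, stem_len=ts, loop_len=tl, pairs=tp),
        tv_loop=not t_present,
        variable_arm_len=v,
        score=score,
    )


def classify_truncation(structure: TrnaStructure) -> List[str]:
    """Truncation labels for a folded tRNA; canonical structures get none."""
    labels: List[str] = []
    if not structure.d_arm.present:
        labels.append(D_ARM_MISSING)
    if structure.tv_loop or not structure.t_arm.present:
        labels.append(T_ARM_MISSING)
    elif structure.t_arm.stem_len + structure.t_arm.loop_len <= SHORT_T_ARM_MAX:
        labels.append(SHORT_T_ARM)
    if not structure.tv_loop:
        v = structure.variable_arm_len
        if v == 0:
            labels.append(NO_VARIABLE_ARM)
        elif v <= SHORT_VARIABLE_MAX:
            labels.append(SHORT_VARIABLE_ARM)
        elif v >= LONG_VARIABLE_MIN:
            labels.append(LONG_VARIABLE_ARM)
    return labels
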
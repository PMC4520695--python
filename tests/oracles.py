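"""Independent brute-force oracles and tiny helpers shared by the tests.

Everything here is deliberately written as plain nested loops over
substrings / neighbour pairs, independent of the package's vectorized or
canonicalized implementations.
"""

from __future__ import annotations

import numpy as np

MARGINAL = [0.474, 0.383, 0.081, 0.062]   # A, T, C, G
ANTICODONS = [
    "TTG", "CAT", "TCA", "TGC", "AAT", "GAA", "TTC", "TCT", "ATT", "TCG",
    "GCA", "ATA", "TCC", "TTT", "GTC", "TAA", "GTG", "TGT", "TGG", "TGA",
    "TAC",
]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ATCG"), size=n, p=MARGINAL))


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _primitive(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def tandem_oracle(s: str, min_p=2, max_p=12, min_copies=3):
    """All maximal perfect primitive tandem runs, non-nested, as
    (start, end, period) tuples - a plain-loop re-derivation."""
    n = len(s)
    hits = []
    for p in range(min_p, max_p + 1):
        matches = [s[i] == s[i - p] for i in range(p, n)]
        runs = []
        start = None
        for k, m in enumerate(matches):
            if m and start is None:
                start = k
            if not m and start is not None:
                runs.append((start, k - 1))
                start = None
        if start is not None:
            runs.append((start, len(matches) - 1))
        for a, b in runs:
            st, en = a, b + p + 1
            if (en - st) / p < min_copies:
                continue
            if not _primitive(s[st : st + p]):
                continue
            hits.append((st, en, p))
    hits.sort(key=lambda h: (-((h[1] - h[0]) / h[2]), h[2], h[0]))
    accepted = []
    for h in hits:
        if any(g[0] <= h[0] and h[1] <= g[1] for g in accepted):
            continue
        accepted.append(h)
    return sorted(accepted)


def conserved_oracle(query, reference) -> int:
    """Conserved oriented boundaries by direct neighbour-pair comparison.

    query/reference: lists of (name, sign). A query pair (x, y) is conserved
    when (x, y) occurs consecutively in the reference, or (flip y, flip x)
    does (the same junction read the other way).
    """
    flip = {"+": "-", "-": "+"}
    n = len(reference)
    ref_pairs = set()
    for i in range(n):
        a, b = reference[i], reference[(i + 1) % n]
        ref_pairs.add((a, b))
        ref_pairs.add(((b[0], flip[b[1]]), (a[0], flip[a[1]])))
    count = 0
    m = len(query)
    for i in range(m):
        if (query[i], query[(i + 1) % m]) in ref_pairs:
            count += 1
    return count


def hairpin_oracle(s: str, min_stem: int, loop_range=(3, 30), allow_gu=True):
    """Longest perfect hairpin stem over all (start, stem, loop) partitions."""
    pairs = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
    if allow_gu:
        pairs |= {("G", "T"), ("T", "G")}
    n = len(s)
    best = None
    for a1 in range(n):
        for stem in range(min_stem, (n - loop_range[0]) // 2 + 1):
            for loop in range(loop_range[0], loop_range[1] + 1):
                end = a1 + 2 * stem + loop
                if end > n:
                    break
                if all((s[a1 + k], s[end - 1 - k]) in pairs for k in range(stem)):
                    if best is None or stem > best:
                        best = stem
    return best
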
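"""Signed circular gene-order comparison.

A mitogenome's gene order is modelled as a circular list of (gene,
orientation) with ``+`` meaning the major (J) strand. Conservation is
measured on *oriented adjacencies*: a neighbouring pair read in either
direction is the same boundary, so the pair (A+, B+) is identical to
(B-, A-). The breakpoint distance is ``n_genes - conserved_boundaries``.

Two block notions are supported. In oriented mode a conserved block is a
maximal run appearing in both orders identically or fully reversed with all
orientations flipped (a signed inversion). In unsigned mode orientations are
ignored and a reversed run counts as inverted; this matches how published
annotation tables describe blocks that were "translocated and inverted en
masse" - after heavy rearrangement each genome's major strand is re-anchored,
so the printed strand labels of a physically inverted block may not flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

Signed = Tuple[str, str]   # (gene name, "+" | "-")

_FLIP = {"+": "-", "-": "+"}


def _flip(g: Signed) -> Signed:
    return (g[0], _FLIP[g[1]])


@dataclass(frozen=True)
class SignedGeneOrder:
    """A circular list of (gene, orientation); equality is rotation-invariant."""

    genes: Tuple[Signed, ...]

    def __post_init__(self):
        names = [g for g, _ in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in order")
        for _, s in self.genes:
            if s not in ("+", "-"):
                raise ValueError(f"orientation must be + or -, got {s!r}")

    @classmethod
    def from_pairs(cls, pairs: Sequence[Signed]) -> "SignedGeneOrder":
        return cls(tuple((str(n), str(s)) for n, s in pairs))

    @classmethod
    def from_record(cls, record, categories=("PCG", "tRNA", "rRNA", "control_region")):
        pairs = [
            (f.name, "+" if f.strand == "J" else "-")
            for f in record.features
            if f.category in categories
        ]
        return cls.from_pairs(pairs)

    def __len__(self) -> int:
        return len(self.genes)

    def names(self) -> set:
        return {g for g, _ in self.genes}

    def rotated(self, k: int) -> "SignedGeneOrder":
        k %= len(self.genes)
        return SignedGeneOrder(self.genes[k:] + self.genes[:k])

    def reversed_reading(self) -> "SignedGeneOrder":
        """The same circle read in the opposite direction."""
        return SignedGeneOrder(tuple(_flip(g) for g in reversed(self.genes)))

    def canonical(self) -> Tuple[Signed, ...]:
        rots = [self.genes[k:] + self.genes[:k] for k in range(len(self.genes))]
        return min(rots)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignedGeneOrder):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def orientation(self, name: str) -> str:
        for g, s in self.genes:
            if g == name:
                return s
        raise KeyError(name)


def _canonical_adj(x: Signed, y: Signed):
    fwd = (x, y)
    rev = (_flip(y), _flip(x))
    return min(fwd, rev)


def oriented_adjacencies(order: SignedGeneOrder) -> set:
    """Canonical oriented adjacency set of a circular signed order."""
    genes = order.genes
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    n = len(genes)
    return {_canonical_adj(genes[i], genes[(i + 1) % n]) for i in range(n)}


def unsigned_adjacencies(order: SignedGeneOrder) -> set:
    genes = [g for g, _ in order.genes]
    n = len(genes)
    return {frozenset((genes[i], genes[(i + 1) % n])) for i in range(n)}


def _check_universe(query: SignedGeneOrder, reference: SignedGeneOrder):
    if query.names() != reference.names():
        only_q = sorted(query.names() - reference.names())
        only_r = sorted(reference.names() - query.names())
        raise ValueError(
            f"gene universes differ: only in query {only_q}, only in reference {only_r}"
        )


def conserved_boundaries(
    query: SignedGeneOrder,
    reference: SignedGeneOrder,
    ignore_orientation: bool = False,
) -> Tuple[int, list]:
    """Count and list the gene boundaries shared with the reference."""
    _check_universe(query, reference)
    if ignore_orientation:
        shared = unsigned_adjacencies(query) & unsigned_adjacencies(reference)
        listing = sorted(tuple(sorted(fs)) for fs in shared)
    else:
        shared = oriented_adjacencies(query) & oriented_adjacencies(reference)
        listing = sorted(shared)
    return len(shared), listing


def breakpoint_distance(
    query: SignedGeneOrder,
    reference: SignedGeneOrder,
    ignore_orientation: bool = False,
) -> int:
    count, _ = conserved_boundaries(query, reference, ignore_orientation)
    return len(query) - count


# ---------------------------------------------------------------------------
# Per-gene rearrangement classes
# ---------------------------------------------------------------------------

CONSERVED = "conserved"
LOCAL_INVERSION = "local_inversion"
TRANSLOCATION = "translocation"
REMOTE_INVERSION = "remote_inversion"


@dataclass
class Block:
    genes: Tuple[str, ...]
    inverted: bool


@dataclass
class RearrangementReport:
    per_gene: Dict[str, str]
    conserved_boundaries: int
    conserved_boundaries_unsigned: int
    boundary_list: list
    blocks: List[Block]                 # oriented-mode blocks
    blocks_unsigned: List[Block]        # written-order blocks (strand labels ignored)
    breakpoints: int
    category_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def rearranged_genes(self, categories: Optional[Sequence[str]] = None) -> List[str]:
        genes = [g for g, cls in self.per_gene.items() if cls != CONSERVED]
        if categories is not None:
            genes = [g for g in genes if default_category(g) in categories]
        return sorted(genes)


def default_category(name: str) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name in ("16S", "12S"):
        return "rRNA"
    if name == "CR":
        return "control_region"
    return "PCG"


def _query_reading(query: SignedGeneOrder, reference: SignedGeneOrder) -> SignedGeneOrder:
    """Choose the query reading direction that best aligns orientations.

    An exact tie is broken by the lexicographically smaller canonical
    rotation, so both readings of the same circle resolve identically.
    """
    ref = dict(reference.genes)
    same = sum(1 for g, s in query.genes if ref[g] == s)
    n = len(query.genes)
    if 2 * same > n:
        return query
    if 2 * same < n:
        return query.reversed_reading()
    flipped = query.reversed_reading()
    return query if query.canonical() <= flipped.canonical() else flipped


def classify_rearrangements(
    query: SignedGeneOrder, reference: SignedGeneOrder
) -> RearrangementReport:
    """Classify every gene as conserved / locally inverted / translocated /
    remotely inverted relative to the reference order.

    A gene keeping at least one of its oriented boundaries is conserved; a
    gene whose boundaries are restored by flipping it in place is a local
    inversion; otherwise it moved, and its orientation (after choosing the
    query reading direction that best matches the reference) separates
    translocation from remote inversion.
    """
    _check_universe(query, reference)
    q = _query_reading(query, reference)
    ref_adj = oriented_adjacencies(reference)
    ref_sign = dict(reference.genes)
    n = len(q.genes)
    per_gene: Dict[str, str] = {}
    for i, gene in enumerate(q.genes):
        left, right = q.genes[(i - 1) % n], q.genes[(i + 1) % n]
        as_is = (_canonical_adj(left, gene), _canonical_adj(gene, right))
        if any(adj in ref_adj for adj in as_is):
            per_gene[gene[0]] = CONSERVED
            continue
        flipped = _flip(gene)
        flipped_adj = (_canonical_adj(left, flipped), _canonical_adj(flipped, right))
        if any(adj in ref_adj for adj in flipped_adj):
            per_gene[gene[0]] = LOCAL_INVERSION
        elif gene[1] == ref_sign[gene[0]]:
            per_gene[gene[0]] = TRANSLOCATION
        else:
            per_gene[gene[0]] = REMOTE_INVERSION

    count, listing = conserved_boundaries(query, reference)
    count_unsigned, _ = conserved_boundaries(query, reference, ignore_orientation=True)
    cat_counts: Dict[str, Dict[str, int]] = {}
    for gene, cls in per_gene.items():
        cat = default_category(gene)
        cat_counts.setdefault(cat, {}).setdefault(cls, 0)
        cat_counts[cat][cls] += 1
    return RearrangementReport(
        per_gene=per_gene,
        conserved_boundaries=count,
        conserved_boundaries_unsigned=count_unsigned,
        boundary_list=listing,
        blocks=find_conserved_blocks(query, reference),
        blocks_unsigned=find_conserved_blocks(query, reference, ignore_orientation=True),
        breakpoints=breakpoint_distance(query, reference),
        category_counts=cat_counts,
    )


# ---------------------------------------------------------------------------
# Conserved blocks
# ---------------------------------------------------------------------------

def find_conserved_blocks(
    query: SignedGeneOrder,
    reference: SignedGeneOrder,
    min_len: int = 2,
    ignore_orientation: bool = False,
) -> List[Block]:
    """Maximal runs shared by both circular orders.

    Oriented mode: a run matches identically (same order, same orientations)
    or as a signed inversion (reversed order, all orientations flipped).
    Unsigned mode: orientations are ignored; a reversed run is inverted.
    """
    _check_universe(query, reference)
    n = len(query.genes)
    ref_pos = {g: (i, s) for i, (g, s) in enumerate(reference.genes)}

    def link_type(i: int) -> Optional[str]:
        """Run type continuing from query position i to i+1, else None."""
        (g1, s1), (g2, s2) = query.genes[i], query.genes[(i + 1) % n]
        p1, r1 = ref_pos[g1]
        p2, r2 = ref_pos[g2]
        fwd_pos = p2 == (p1 + 1) % n
        rev_pos = p2 == (p1 - 1) % n
        if ignore_orientation:
            if fwd_pos:
                return "F"
            if rev_pos:
                return "R"
            return None
        if fwd_pos and s1 == r1 and s2 == r2:
            return "F"
        if rev_pos and s1 == _FLIP[r1] and s2 == _FLIP[r2]:
            return "R"
        return None

    links = [link_type(i) for i in range(n)]
    if all(l is None for l in links):
        return []
    if all(l == "F" for l in links):
        return [Block(genes=tuple(g for g, _ in query.genes), inverted=False)]
    if all(l == "R" for l in links):
        return [Block(genes=tuple(g for g, _ in query.genes), inverted=True)]

    # decompose the circular link array into maximal same-type segments
    anchor = next(i for i in range(n) if links[i] != links[(i - 1) % n])
    blocks: List[Block] = []
    i = anchor
    steps = 0
    while steps < n:
        t = links[i]
        j = i
        length = 1
        while length < n and links[(j + 1) % n] == t:
            j = (j + 1) % n
            length += 1
        if t is not None:
            genes = tuple(query.genes[(i + k) % n][0] for k in range(length + 1))
            if len(genes) >= min_len:
                blocks.append(Block(genes=genes, inverted=(t == "R")))
        steps += length
        i = (i + length) % n
    return blocks
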
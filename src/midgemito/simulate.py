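"""Synthetic gall-midge mitogenomes with known ground truth.

The generator emits ~15.3 kb circular genomes with the full 37-gene gall-midge
gene order and strands, the two intergenic repeat regions (RR-I between trnW
and trnA, RR-II between trnI and COI) parameterized by the published
biotype-specific iteration counts, a control region carrying the five
conserved structural elements in canonical order, and tRNAs built arm-by-arm
with the published truncations (TV loops, missing D-arms, a shortened T-arm).

Stated-world choices (see docs/methods.md for rationale):

* bases are drawn i.i.d. from the published whole-genome marginal
  (A .474 / T .383 / C .081 / G .062), rescaled to the requested A+T target;
* PCG interiors are random sense codons of the invertebrate mitochondrial
  code - no homology to real genes is attempted;
* non-repeat spacers are rejection-screened to contain no tandem array of
  >= 3 copies at periods 2-12, and each planted array is flanked by "guard"
  edits ensuring the detected array boundary is exactly the planted one;
* rRNA interiors are the calibration reservoir: their A+T rate is solved
  after all constrained parts are built so the whole genome hits the target;
* the control region is assembled element-by-element and re-scanned after
  assembly; fillers are resampled until the scan recovers exactly the
  planted elements (a "clean canonical CR" stated world).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import reference as ref
from .control_region import CRScanParams, scan_control_region
from .model import (
    GeneAnnotation,
    MitogenomeRecord,
    NucleotideSequence,
    reverse_complement,
)
from .repeats import find_tandem_repeats

BASES = np.array(list("ATCG"))

_SENSE_CODONS: Optional[List[str]] = None


def _sense_codons() -> List[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from .composition import sense_codons

        _SENSE_CODONS = sense_codons()
    return _SENSE_CODONS


@dataclass
class SyntheticGenomeSpec:
    """Parameters of one synthetic genome (defaults are the published world)."""

    biotype: str = "GMB1"
    gene_order_template: str = "oryzae"    # or "ancestral" or a custom list
    target_at_fraction: float = 0.857
    repeat_overrides: Optional[Dict[str, float]] = None
    seed: int = 0
    cr_ta_copies: int = 12
    custom_order: Optional[List[str]] = None

    def __post_init__(self):
        if self.biotype not in ref.BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if not (0.0 < self.target_at_fraction < 1.0):
            raise ValueError("target_at_fraction must be in (0, 1)")
        if self.repeat_overrides:
            for motif, count in self.repeat_overrides.items():
                if count is not None and count < 0:
                    raise ValueError(f"negative repeat count for {motif!r}")


# ---------------------------------------------------------------------------
# base-level sampling helpers
# ---------------------------------------------------------------------------

def _base_probs(at: float) -> np.ndarray:
    a = at * ref.BASE_COMPOSITION["A"] / (ref.BASE_COMPOSITION["A"] + ref.BASE_COMPOSITION["T"])
    t = at - a
    c = (1 - at) * ref.BASE_COMPOSITION["C"] / (ref.BASE_COMPOSITION["C"] + ref.BASE_COMPOSITION["G"])
    g = (1 - at) - c
    return np.array([a, t, c, g])


def _sample(rng: np.random.Generator, n: int, at: float) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(BASES, size=n, p=_base_probs(at)))


def _screened_spacer(rng: np.random.Generator, n: int, at: float) -> str:
    """Random spacer free of tandem arrays (>= 3 copies, period 2-12)."""
    for _ in range(500):
        s = _sample(rng, n, at)
        if not find_tandem_repeats(s, 2, 12, min_copies=3, max_mismatch_frac=0.1):
            return s
    raise RuntimeError(f"could not screen a {n} bp spacer")


# ---------------------------------------------------------------------------
# repeat loci
# ---------------------------------------------------------------------------

def _resolve_count(value, rng: np.random.Generator, policy: str = "midpoint"):
    """A key-table count entry -> concrete count(s).

    int/float -> itself; (lo, hi) range -> midpoint (or a uniform draw when
    policy == "draw"); [a, b] list -> composite segment counts.
    """
    if isinstance(value, tuple):
        lo, hi = value
        if policy == "draw":
            return int(rng.integers(lo, hi + 1))
        return int((lo + hi) // 2)
    return value


def _array_seq(motif: str, copies: float) -> str:
    full = int(copies)
    partial = int(round((copies - full) * len(motif)))
    return motif * full + motif[:partial]


def _guard_boundaries(seq: bytearray, arrays: List[Tuple[int, int, int]]) -> None:
    """Edit spacer bases flanking each planted array so the self-match run
    ends exactly at the planted boundary (no accidental extension/bridging).
    """
    n = len(seq)
    forbidden: Dict[int, set] = {}
    for start, end, p in arrays:
        for tt in range(p):
            i = end + tt
            if i < n and not any(s <= i < e for s, e, _ in arrays):
                forbidden.setdefault(i, set()).add(seq[i - p])
            i = start - 1 - tt
            if i >= 0 and not any(s <= i < e for s, e, _ in arrays):
                forbidden.setdefault(i, set()).add(seq[i + p])
    for i, bad in forbidden.items():
        if seq[i] in bad:
            for b in b"CGTA":
                if b not in bad:
                    seq[i] = b
                    break


def _build_repeat_locus(
    rng: np.random.Generator,
    arrays: List[Tuple[str, int]],
    at: float,
    absent_len: int = 80,
    spacer_len: int = 25,
) -> Tuple[str, List[Tuple[int, int, int]]]:
    """Concatenate planted (array, period) pieces with screened, guarded
    spacers. Returns (locus sequence, [(start, end, period), ...]).
    """
    if not arrays:
        return _screened_spacer(rng, absent_len, at), []
    parts = [_screened_spacer(rng, spacer_len, at)]
    spans = []
    pos = spacer_len
    for arr, period in arrays:
        parts.append(arr)
        spans.append((pos, pos + len(arr), period))
        parts.append(_screened_spacer(rng, spacer_len, at))
        pos += len(arr) + spacer_len
    locus = bytearray("".join(parts), "ascii")
    _guard_boundaries(locus, spans)
    return locus.decode(), spans


def _biotype_arrays(
    biotype: str,
    rng: np.random.Generator,
    overrides: Optional[Dict[str, float]] = None,
    gmb4_policy: str = "midpoint",
) -> Tuple[List[Tuple[str, object]], Optional[float], int]:
    """(RR-I motif/count entries, RR-II copies, RR-II variant copies)."""
    entry = ref.REPEAT_KEY_TABLE[biotype]
    overrides = overrides or {}
    rr1 = []
    for motif in ref.RR1_MOTIFS:
        if motif in overrides:
            value = overrides[motif]
        elif motif in entry["rr1"]:
            value = entry["rr1"][motif]
        else:
            continue
        if value is None:
            continue
        if isinstance(value, tuple):
            policy = gmb4_policy if (biotype == "GMB4" and motif == "TAAAT") else "midpoint"
            value = _resolve_count(value, rng, policy)
        rr1.append((motif, value))
    rr2 = overrides.get("rr2", entry.get("rr2"))
    variant = entry.get("rr2_variant_copies", 0)
    return rr1, rr2, variant


def _rr1_locus(rng, rr1_entries, at):
    arrays, truth = [], []
    for motif, value in rr1_entries:
        if isinstance(value, list):        # interrupted composite array
            for seg_copies in value:
                arrays.append((_array_seq(motif, seg_copies), len(motif)))
            truth.append({"motif": motif, "segments": [float(v) for v in value],
                          "copies": float(sum(value))})
        else:
            arrays.append((_array_seq(motif, float(value)), len(motif)))
            truth.append({"motif": motif, "segments": [float(value)],
                          "copies": float(value)})
    locus, spans = _build_repeat_locus(rng, arrays, at)
    return locus, truth, spans


def _rr2_locus(rng, rr2_copies, variant_copies, at):
    if rr2_copies is None:
        return _screened_spacer(rng, 120, at), None, []
    motif = ref.RR2_MOTIF
    arr = _array_seq(motif, float(rr2_copies))
    if variant_copies:
        copies = [arr[i * 12 : (i + 1) * 12] for i in range(int(rr2_copies))]
        # the variant copies sit mid-array (positions 2, 3 for two copies)
        for k in range(variant_copies):
            copies[2 + k] = ref.RR2_VARIANT_MOTIF
        arr = "".join(copies) + arr[int(rr2_copies) * 12 :]
    locus, spans = _build_repeat_locus(rng, [(arr, 12)], at)
    truth = {
        "motif": motif,
        "copies": float(rr2_copies),
        "variant_copies": int(variant_copies),
    }
    return locus, truth, spans


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

def _build_pcg(rng: np.random.Generator, size: int, start_codon: str,
               stop_codon: str, at: float) -> str:
    assert size % 3 == 0
    codons = _sense_codons()
    probs = _base_probs(at)
    base_p = dict(zip("ATCG", probs))
    weights = np.array([
        base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in codons
    ])
    weights /= weights.sum()
    n_codons = size // 3 - 2
    body = "".join(rng.choice(np.array(codons), size=n_codons, p=weights))
    return start_codon + body + stop_codon


def _build_trna(
    rng: np.random.Generator,
    anticodon: str,
    at: float,
    d_arm: bool = True,
    t_arm: bool = True,
    tv_loop: bool = False,
    var_len: int = 4,
    t_stem: int = 4,
    t_loop: int = 5,
) -> Tuple[str, dict]:
    """Assemble a tRNA arm-by-arm; stems pair perfectly by construction."""
    def stem(k):
        return _sample(rng, k, at)

    acc = stem(7)
    parts = [acc, _sample(rng, 2, at)]
    if d_arm:
        d5 = stem(4)
        parts += [d5, _sample(rng, int(rng.integers(5, 8)), at), reverse_complement(d5)]
    else:
        parts.append(_sample(rng, 5, at))    # D-arm replaced by a short loop
    parts.append(_sample(rng, 1, at))
    c5 = stem(5)
    parts += [c5, _sample(rng, 2, at), anticodon, _sample(rng, 2, at),
              reverse_complement(c5)]
    if tv_loop or not t_arm:
        parts.append(_sample(rng, 8, at))    # single TV loop
        t_present = False
    else:
        parts.append(_sample(rng, var_len, at))
        t5 = stem(t_stem)
        parts += [t5, _sample(rng, t_loop, at), reverse_complement(t5)]
        t_present = True
    parts.append(reverse_complement(acc))
    seq = "".join(parts)
    truth = {
        "anticodon": anticodon,
        "d_arm": d_arm,
        "t_arm": t_present,
        "tv_loop": not t_present,
        "variable_arm_len": 0 if not t_present else var_len,
    }
    return seq, truth


def _trna_layout(name: str, table_var) -> dict:
    layout = {"d_arm": name not in ref.D_ARM_MISSING, "t_arm": True,
              "tv_loop": False, "var_len": 4, "t_stem": 4, "t_loop": 5}
    if name in ref.TV_LOOP or table_var == "TV":
        layout.update(tv_loop=True, t_arm=False)
    if name in ref.SHORT_T_ARM:
        layout.update(t_stem=3, t_loop=3)
    if isinstance(table_var, int):
        layout["var_len"] = table_var
    return layout


# ---------------------------------------------------------------------------
# control region
# ---------------------------------------------------------------------------

def _cr_filler(rng, n, at, forbid_tata=False):
    """CR filler screened/repaired so it cannot mimic a planted element."""
    import re

    if n <= 0:
        return ""
    pattern = re.compile(r"T{4,}|(?:TA){3,}" + ("|TATA" if forbid_tata else ""))
    s = list(_sample(rng, n, at))
    for _ in range(50):
        m = pattern.search("".join(s))
        if not m:
            break
        s[m.start() + (m.end() - m.start()) // 2] = "C"
    return "".join(s)


def _assemble_cr(rng, ta_copies, at, length):
    """One CR assembly attempt; returns (sequence, element truth spans)."""
    stem_arm = _sample(rng, 16, at)
    pieces = []
    truth = {}

    def add(piece, name=None):
        start = sum(len(p) for p in pieces)
        pieces.append(piece)
        if name:
            truth[name] = (start, start + len(piece))

    add(_cr_filler(rng, 15, at))
    add("C")
    add("T" * 10, "poly_t")
    add("C")
    add(_cr_filler(rng, 12, at))
    add("C")
    add("TA" * ta_copies, "ta_tract")
    add("C")
    add(_cr_filler(rng, 8, at, forbid_tata=True))
    add("TATA", "consensus_5p")
    add(_cr_filler(rng, 6, at, forbid_tata=True))
    add(stem_arm + _sample(rng, 10, at) + reverse_complement(stem_arm),
        "stem_loop")
    add("G" + "A" * 5 + "T", "consensus_3p")
    add("TTCTTCT")
    ga = "".join(rng.choice(np.array(list("AG")), size=32, p=[0.65, 0.35]))
    add(ga, "ga_rich")
    add("TCTTCTT")
    remaining = length - sum(len(p) for p in pieces)
    add(_cr_filler(rng, remaining, at))
    truth["ta_copies"] = ta_copies
    return "".join(pieces), truth


def _spans_close(a, b, tol=2):
    return abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol


def _build_cr(rng, ta_copies, at, length=ref.CONTROL_REGION_LENGTH):
    """Assemble a control region and verify its elements scan back cleanly."""
    for _ in range(50):
        seq, truth = _assemble_cr(rng, ta_copies, at, length)
        ann = scan_control_region(seq, CRScanParams())
        recovered = {
            "poly_t": ann.poly_t,
            "ta_tract": ann.ta_tract,
            "consensus_5p": ann.consensus_5p,
            "consensus_3p": ann.consensus_3p,
            "ga_rich": ann.ga_rich,
            "stem_loop": ann.stem_loop.span if ann.stem_loop else None,
        }
        if ann.order_conserved and all(
            recovered[k] is not None and _spans_close(recovered[k], truth[k])
            for k in ("poly_t", "ta_tract", "stem_loop",
                      "consensus_5p", "consensus_3p", "ga_rich")
        ):
            return seq, truth
    raise RuntimeError("could not assemble a clean control region")


# ---------------------------------------------------------------------------
# whole-genome assembly
# ---------------------------------------------------------------------------

def generate_mitogenome(
    spec: SyntheticGenomeSpec, _gmb4_policy: str = "midpoint"
) -> Tuple[MitogenomeRecord, dict]:
    """Generate one genome plus its ground-truth annotation dictionary."""
    rng = np.random.default_rng(spec.seed)
    at = spec.target_at_fraction

    rr1_entries, rr2_copies, rr2_variant = _biotype_arrays(
        spec.biotype, rng, spec.repeat_overrides, _gmb4_policy
    )
    rr1_seq, rr1_truth, rr1_spans = _rr1_locus(rng, rr1_entries, at)
    rr2_seq, rr2_truth, rr2_spans = _rr2_locus(rng, rr2_copies, rr2_variant, at)
    cr_seq, cr_truth = _build_cr(rng, spec.cr_ta_copies, at)

    template = list(ref.ORYZAE_ANNOTATION)
    if spec.gene_order_template == "custom" and spec.custom_order:
        by_name = {row[0]: row for row in ref.ORYZAE_ANNOTATION}
        template = [by_name[n] for n in spec.custom_order]

    # pass 1: build all constrained segments in template order
    segments: List[Tuple[str, Optional[tuple]]] = []   # (seq or None, meta)
    trna_truth: Dict[str, dict] = {}
    rrna_sizes: Dict[int, int] = {}
    for idx, (name, cat, strand, size, anticodon, start_c, stop_c, var) in enumerate(template):
        if cat == "repeat_region":
            segment = rr1_seq if name == "RR-I" else rr2_seq
        elif cat == "control_region":
            segment = cr_seq
        elif cat == "PCG":
            segment = _build_pcg(rng, size, start_c, stop_c, at)
        elif cat == "tRNA":
            segment, t_truth = _build_trna(rng, anticodon, at, **_trna_layout(name, var))
            trna_truth[name] = t_truth
        elif cat == "rRNA":
            segment = None                  # calibration reservoir, pass 2
            rrna_sizes[idx] = size
        meta = (name, cat, strand, anticodon, start_c, stop_c, var)
        segments.append((segment, meta))
        if idx < len(template) - 1:
            spacer = _sample(rng, int(rng.integers(3, 12)), at)
            segments.append((spacer, None))

    # composition calibration: solve the rRNA A+T rate to hit the target
    built = "".join(s for s, _ in segments if s is not None)
    at_built = sum(built.count(b) for b in "AT")
    rrna_total = sum(rrna_sizes.values())
    total_len = len(built) + rrna_total
    need = spec.target_at_fraction * total_len - at_built
    rrna_at = min(0.98, max(0.70, need / rrna_total))
    filled: List[Tuple[str, Optional[tuple]]] = []
    for i, (s, meta) in enumerate(segments):
        if s is None:
            size = rrna_sizes[sum(1 for ss, mm in segments[:i] if mm is not None)]
            s = _sample(rng, size, rrna_at)
        filled.append((s, meta))

    # assemble, reverse-complementing N-strand features into the J strand
    genome_parts: List[str] = []
    features: List[GeneAnnotation] = []
    truth: dict = {
        "biotype": spec.biotype,
        "rr1": rr1_truth,
        "rr2": rr2_truth,
        "trna": trna_truth,
        "cr": cr_truth,
        "repeat_spans": [],
    }
    pos = 0
    for s, meta in filled:
        if meta is None:
            genome_parts.append(s)
            pos += len(s)
            continue
        name, cat, strand, anticodon, start_c, stop_c, var = meta
        placed = reverse_complement(s) if strand == "N" else s
        genome_parts.append(placed)
        features.append(
            GeneAnnotation(
                name=name,
                category=cat,
                strand=strand,
                start=pos,
                end=pos + len(s),
                anticodon=anticodon if cat == "tRNA" else None,
                start_codon=start_c,
                stop_codon=stop_c,
                variable_arm_len=var if isinstance(var, int) else None,
            )
        )
        if cat == "repeat_region":
            spans = rr1_spans if name == "RR-I" else rr2_spans
            for (a, b, period) in spans:
                truth["repeat_spans"].append(
                    {"locus": name, "start": pos + a, "end": pos + b,
                     "period": period}
                )
        if cat == "control_region":
            truth["cr_start"] = pos
        pos += len(s)

    genome = "".join(genome_parts)
    record = MitogenomeRecord(
        id=f"synthetic_{spec.biotype}_seed{spec.seed}",
        sequence=NucleotideSequence(genome, is_circular=True),
        features=features,
    )
    truth["length"] = len(genome)
    truth["at_realized"] = (genome.count("A") + genome.count("T")) / len(genome)
    assert 14000 <= len(genome) <= 16500, "genome length out of bounds"
    return record, truth


def generate_biotype_panel(seed: int) -> List[Tuple[MitogenomeRecord, dict]]:
    """One genome per published repeat-table row (7 biotypes + 2 species).

    GMB4's TAAAT count is drawn uniformly from its published 30-33 range;
    other printed ranges use their midpoints.
    """
    panel = []
    for i, biotype in enumerate(ref.BIOTYPES):
        spec = SyntheticGenomeSpec(biotype=biotype, seed=seed * 101 + i)
        panel.append(generate_mitogenome(spec, _gmb4_policy="draw"))
    return panel


def mutate(
    record: MitogenomeRecord,
    subst_rate: float,
    seed: int,
    truth: Optional[dict] = None,
) -> MitogenomeRecord:
    """Apply point substitutions, sparing each planted array's first and
    last copy so array boundaries (and motif phase) stay intact."""
    if not (0.0 <= subst_rate <= 0.05):
        raise ValueError("substitution rate must be within [0, 0.05]")
    rng = np.random.default_rng(seed)
    seq = np.array(list(record.sequence.residues))
    n = len(seq)
    protected = np.zeros(n, dtype=bool)
    if truth:
        for span in truth.get("repeat_spans", []):
            p = span["period"]
            protected[span["start"] : span["start"] + p] = True
            protected[max(span["start"], span["end"] - p) : span["end"]] = True
    hit = (rng.random(n) < subst_rate) & ~protected
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = choices[rng.integers(0, 3)]
    return MitogenomeRecord(
        id=record.id + f"_mut{subst_rate}",
        sequence=NucleotideSequence("".join(seq), is_circular=record.sequence.is_circular),
        features=[replace(f) for f in record.features],
    )
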
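"""Primer design on riboprobe templates and in-silico PCR verification.

The riboprobe amplicon is a 500-800 bp PCR product inside the template
region; the reverse primer carries a T7 RNA-polymerase promoter tag so
the product templates antisense RNA synthesis.  Design is a
deterministic exhaustive scan over forward/reverse primer placements
under melting-temperature, GC and homopolymer constraints; specificity
is then checked by brute-force in-silico PCR against a transcript set.

Melting temperature defaults to the Wallace rule, Tm = 2(A+T) + 4(G+C)
degrees C, computed on the primer core only (the T7 tag does not anneal
in the first cycles).  The Tm function is a pluggable strategy: any
callable mapping a sequence to degrees C (e.g. a nearest-neighbour
model) can be passed via ``PrimerConstraints.tm_method``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction

from .errors import PrimerDesignError
from .probemap import TemplateRegion

__all__ = [
    "T7_PROMOTER",
    "PrimerConstraints",
    "PrimerPair",
    "AmpliconPrediction",
    "reverse_complement",
    "melting_temperature",
    "gc_content",
    "max_homopolymer_run",
    "design_primers",
    "insilico_pcr",
]

#: Canonical T7 RNA polymerase promoter, prepended to the reverse primer.
T7_PROMOTER = "TAATACGACTCACTATAGGG"

_VALID_SEQ = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A, C, G, T, N} alphabet."""
    seq = seq.upper()
    if not set(seq) <= _VALID_SEQ:
        bad = sorted(set(seq) - _VALID_SEQ)
        raise ValueError(f"invalid characters {bad} in sequence")
    return str(Seq(seq).reverse_complement())


def melting_temperature(seq: str) -> float:
    """Wallace-rule melting temperature, Tm = 2(A+T) + 4(G+C) in deg C.

    Requires >=10 nt; at primer lengths the rule is deterministic and
    monotone in GC content at fixed length, which is all the design scan
    relies on.
    """
    seq = seq.upper()
    if len(seq) < 10:
        raise ValueError("sequence too short for a meaningful Tm (need >=10 nt)")
    if not set(seq) <= frozenset("ACGT"):
        raise ValueError("Tm defined over ACGT only")
    return float(MeltingTemp.Tm_Wallace(seq))


def gc_content(seq: str) -> float:
    """GC percentage, 100 * (G+C) / length."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * gc_fraction(seq.upper())


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-nucleotide run."""
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


@dataclass(frozen=True)
class PrimerConstraints:
    """Design constraints; defaults follow common riboprobe practice:
    500-800 bp product, 18-27 nt primers, Tm 52-68 deg C (optimum 60),
    GC 40-60%, homopolymer runs of at most 4."""

    product_min: int = 500
    product_max: int = 800
    primer_len_min: int = 18
    primer_len_max: int = 27
    tm_min: float = 52.0
    tm_opt: float = 60.0
    tm_max: float = 68.0
    gc_min: float = 40.0
    gc_max: float = 60.0
    max_homopolymer: int = 4
    t7_tag: str = T7_PROMOTER
    tm_method: Callable[[str], float] = field(default=melting_temperature)

    def __post_init__(self) -> None:
        if not (0 < self.product_min <= self.product_max):
            raise ValueError("need 0 < product_min <= product_max")
        if not (0 < self.primer_len_min <= self.primer_len_max):
            raise ValueError("need 0 < primer_len_min <= primer_len_max")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("need tm_min <= tm_opt <= tm_max")
        if not (0 <= self.gc_min <= self.gc_max <= 100):
            raise ValueError("need 0 <= gc_min <= gc_max <= 100")


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair.  ``reverse_tagged_seq`` is the T7-tagged oligo to
    order; Tm and GC refer to the annealing cores.  Product coordinates
    are 0-based half-open on the template's transcript."""

    forward_seq: str
    reverse_core_seq: str
    reverse_tagged_seq: str
    forward_tm: float
    reverse_tm: float
    forward_gc: float
    reverse_gc: float
    product_start: int
    product_end: int
    product_length: int


@dataclass(frozen=True)
class AmpliconPrediction:
    """One product an exhaustive in-silico PCR predicts: convergent
    forward/reverse annealing sites on one transcript."""

    transcript_id: str
    start: int
    end: int
    length: int
    forward_orientation: str = "sense"
    convergent: bool = True


def _candidates(sub: str, c: PrimerConstraints, reverse: bool):
    """Feasible primer placements in template-local coordinates.

    Yields ``(pos, length, tm)`` where ``pos`` is the forward primer
    start, or for the reverse primer the product end (the 3'-most
    template base the primer covers, exclusive)."""
    n = len(sub)
    for length in range(c.primer_len_min, c.primer_len_max + 1):
        if reverse:
            positions = range(length, n + 1)
        else:
            positions = range(0, n - length + 1)
        for pos in positions:
            core = sub[pos - length : pos] if reverse else sub[pos : pos + length]
            if reverse:
                core = reverse_complement(core)
            if "N" in core:
                continue
            if not (c.gc_min <= gc_content(core) <= c.gc_max):
                continue
            if max_homopolymer_run(core) > c.max_homopolymer:
                continue
            tm = c.tm_method(core)
            if not (c.tm_min <= tm <= c.tm_max):
                continue
            yield pos, length, tm


def design_primers(
    transcript_seq: str,
    region: TemplateRegion,
    constraints: PrimerConstraints | None = None,
) -> PrimerPair:
    """Deterministic exhaustive primer-pair search inside a template.

    Every feasible (forward start, forward length, product end, reverse
    length) combination within the region is scored by
    ``|fwd Tm - tm_opt| + |rev Tm - tm_opt| + |fwd Tm - rev Tm|``; ties
    go to the larger product end (3' preference), then the shorter
    product, then lexicographically smallest placement.  When the region
    records a probe span, only products containing that span are
    considered, so the riboprobe keeps its physical overlap with the
    probeset.  Raises :class:`PrimerDesignError` naming the binding
    constraint when no pair exists.
    """
    c = constraints or PrimerConstraints()
    sub = transcript_seq[region.start : region.end].upper()
    if len(sub) < c.product_min:
        raise PrimerDesignError(
            f"template length {len(sub)} below minimum product {c.product_min}"
        )
    # probe span in template-local coordinates; product must contain it
    span_lo, span_hi = 0, 0
    if region.probe_span is not None:
        span_lo = max(0, region.probe_span[0] - region.start)
        span_hi = min(len(sub), region.probe_span[1] - region.start)

    forwards = list(_candidates(sub, c, reverse=False))
    if not forwards:
        raise PrimerDesignError(
            "no forward primer satisfies Tm/GC/homopolymer bounds"
        )
    reverses = list(_candidates(sub, c, reverse=True))
    if not reverses:
        raise PrimerDesignError(
            "no reverse primer satisfies Tm/GC/homopolymer bounds"
        )

    # Index forward candidates by start for the product-length window.
    by_start: dict[int, list[tuple[int, int, float]]] = {}
    for s, lf, tm in forwards:
        by_start.setdefault(s, []).append((s, lf, tm))

    best_key = None
    best = None
    for e, lr, rtm in reverses:
        if e < span_hi:
            continue
        for s in range(max(0, e - c.product_max), min(span_lo, e - c.product_min) + 1):
            for s_, lf, ftm in by_start.get(s, ()):
                if s_ + lf > e - lr:  # primers must not overlap
                    continue
                score = abs(ftm - c.tm_opt) + abs(rtm - c.tm_opt) + abs(ftm - rtm)
                key = (score, -e, e - s_, s_, lf, lr)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (s_, lf, ftm, e, lr, rtm)
    if best is None:
        raise PrimerDesignError(
            "forward and reverse candidates exist but no convergent pair "
            f"yields a product of {c.product_min}-{c.product_max} bp"
        )
    s, lf, ftm, e, lr, rtm = best
    fwd = sub[s : s + lf]
    rev_core = reverse_complement(sub[e - lr : e])
    return PrimerPair(
        forward_seq=fwd,
        reverse_core_seq=rev_core,
        reverse_tagged_seq=c.t7_tag + rev_core,
        forward_tm=ftm,
        reverse_tm=rtm,
        forward_gc=gc_content(fwd),
        reverse_gc=gc_content(rev_core),
        product_start=region.start + s,
        product_end=region.start + e,
        product_length=e - s,
    )


def insilico_pcr(
    pair: PrimerPair,
    transcripts: Mapping[str, str],
    max_product: int = 5000,
) -> list[AmpliconPrediction]:
    """Predict every product the pair would amplify from a sequence set.

    Brute force: the forward primer is matched exactly on the sense
    strand; the reverse *core* anneals where its reverse complement
    occurs downstream.  Every convergent, non-overlapping pairing with a
    product of at most ``max_product`` bp is reported, ordered by
    (transcript id, start, end).  Exact matching, no mismatch allowance.
    """
    fwd = pair.forward_seq.upper()
    rev_site = reverse_complement(pair.reverse_core_seq)
    out: list[AmpliconPrediction] = []
    for tid in sorted(transcripts):
        seq = transcripts[tid].upper()
        fwd_starts = _find_all_positions(seq, fwd)
        rev_starts = _find_all_positions(seq, rev_site)
        for fs in fwd_starts:
            for rs in rev_starts:
                if rs < fs + len(fwd):
                    continue  # not convergent / overlapping
                end = rs + len(rev_site)
                if end - fs > max_product:
                    continue
                out.append(AmpliconPrediction(tid, fs, end, end - fs))
    out.sort(key=lambda a: (a.transcript_id, a.start, a.end))
    return out


def _find_all_positions(haystack: str, needle: str) -> list[int]:
    positions = []
    pos = haystack.find(needle)
    while pos != -1:
        positions.append(pos)
        pos = haystack.find(needle, pos + 1)
    return positions
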
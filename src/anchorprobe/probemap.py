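"""Mapping of 25-mer array probes onto transcripts and riboprobe
template selection.

A microarray probeset interrogates one transcript with (typically) 11
25-mer oligos.  A riboprobe validates the same signal only if it covers
the same transcript region, so the template for riboprobe PCR is chosen
to physically overlap the probeset: each 25-mer is located on a set of
transcript sequences by exact substring search (both orientations by
default -- array probes may be antisense to the mRNA), the fraction of
distinct probes with at least one hit is the probeset's coverage of that
transcript, and templates are only designed where coverage reaches 80%.

The template itself is the smallest interval containing every probe
hit, grown to the 500-800 bp size a riboprobe needs with growth biased
toward the transcript 3' end (riboprobes target the 3'UTR-proximal
region).  All coordinates are 0-based half-open, BED-native.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import CoverageError, FormatError, TemplateLengthError

__all__ = [
    "PROBE_LENGTH",
    "DEFAULT_PROBESET_SIZE",
    "OligoProbe",
    "ProbeHit",
    "ProbesetMapping",
    "TemplateRegion",
    "read_probes",
    "read_transcripts",
    "write_transcripts",
    "map_probes",
    "coverage_fraction",
    "build_mappings",
    "select_template",
    "rank_probesets",
    "write_template_bed",
]

PROBE_LENGTH = 25
#: Standard probeset size on the expression arrays this models.
DEFAULT_PROBESET_SIZE = 11

_VALID_PROBE = frozenset("ACGT")
_VALID_TRANSCRIPT = frozenset("ACGTN")


@dataclass(frozen=True)
class OligoProbe:
    """One 25-mer oligo of a probeset."""

    probeset_id: str
    probe_index: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != PROBE_LENGTH:
            raise ValueError(
                f"{self.probeset_id}[{self.probe_index}]: probe length "
                f"{len(self.sequence)} != {PROBE_LENGTH}"
            )
        if not set(self.sequence) <= _VALID_PROBE:
            raise ValueError(
                f"{self.probeset_id}[{self.probe_index}]: non-ACGT character"
            )
        if self.probe_index < 0:
            raise ValueError("probe_index must be non-negative")


@dataclass(frozen=True)
class ProbeHit:
    """Exact occurrence of a probe on a transcript (0-based half-open)."""

    probeset_id: str
    probe_index: int
    transcript_id: str
    start: int
    end: int
    orientation: str  # "sense" | "antisense"


@dataclass(frozen=True)
class ProbesetMapping:
    """All hits of one probeset on one transcript plus its coverage, the
    fraction of distinct probe indices with at least one hit."""

    probeset_id: str
    transcript_id: str
    hits: tuple[ProbeHit, ...]
    coverage_fraction: float

    @property
    def span(self) -> tuple[int, int]:
        return (min(h.start for h in self.hits), max(h.end for h in self.hits))


@dataclass(frozen=True)
class TemplateRegion:
    """Chosen riboprobe template interval on a transcript.

    ``probe_span`` is the smallest interval containing the covered probe
    hits; primer design uses it to force the amplicon to overlap the
    probeset."""

    transcript_id: str
    start: int
    end: int
    covered_probe_count: int
    probe_span: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def read_probes(path: str | os.PathLike) -> list[OligoProbe]:
    """Read a probe TSV with columns probeset_id, probe_index, sequence."""
    df = pd.read_csv(path, sep="\t", dtype={"probeset_id": str, "sequence": str})
    required = ["probeset_id", "probe_index", "sequence"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"probe table must start with columns {required}")
    return [
        OligoProbe(str(r.probeset_id), int(r.probe_index), str(r.sequence).upper())
        for r in df.itertuples(index=False)
    ]


def read_transcripts(path: str | os.PathLike) -> dict[str, str]:
    """Read a transcript FASTA into an id -> uppercase sequence map."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate transcript id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for transcript {rec.id!r}")
        if not set(seq) <= _VALID_TRANSCRIPT:
            raise FormatError(f"transcript {rec.id!r} has non-ACGTN characters")
        records[rec.id] = seq
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_transcripts(transcripts: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for tid, seq in transcripts.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


def map_probes(
    probes: Sequence[OligoProbe],
    transcripts: Mapping[str, str],
    allow_antisense: bool = True,
) -> list[ProbeHit]:
    """Exact substring search of every probe against every transcript.

    With ``allow_antisense`` the reverse complement of each probe is
    searched too and such hits are reported with transcript coordinates
    and orientation "antisense".  All occurrences are reported, ordered
    by (transcript id, start, probeset id, probe index).
    """
    hits: list[ProbeHit] = []
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        for probe in probes:
            for start in _find_all(seq, probe.sequence):
                hits.append(
                    ProbeHit(probe.probeset_id, probe.probe_index, tid,
                             start, start + PROBE_LENGTH, "sense")
                )
            if allow_antisense:
                rc = str(Seq(probe.sequence).reverse_complement())
                for start in _find_all(seq, rc):
                    hits.append(
                        ProbeHit(probe.probeset_id, probe.probe_index, tid,
                                 start, start + PROBE_LENGTH, "antisense")
                    )
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.probeset_id, h.probe_index))
    return hits


def coverage_fraction(hits: Sequence[ProbeHit], probeset_size: int) -> float:
    """Distinct probe indices with >=1 hit divided by the probeset size."""
    if probeset_size < 1:
        raise ValueError("probeset_size must be >= 1")
    return len({h.probe_index for h in hits}) / probeset_size


def build_mappings(
    hits: Sequence[ProbeHit],
    probeset_sizes: Mapping[str, int] | int = DEFAULT_PROBESET_SIZE,
) -> list[ProbesetMapping]:
    """Group hits by (probeset, transcript) into mappings with coverage.

    ``probeset_sizes`` is either one size for all probesets or a map
    per probeset id.
    """
    grouped: dict[tuple[str, str], list[ProbeHit]] = {}
    for h in hits:
        grouped.setdefault((h.probeset_id, h.transcript_id), []).append(h)
    out = []
    for (pid, tid), hs in sorted(grouped.items()):
        size = probeset_sizes if isinstance(probeset_sizes, int) else probeset_sizes[pid]
        out.append(
            ProbesetMapping(pid, tid, tuple(hs), coverage_fraction(hs, size))
        )
    return out


def select_template(
    transcripts: Mapping[str, str],
    mapping: ProbesetMapping,
    min_len: int = 500,
    max_len: int = 800,
    min_coverage: float = 0.8,
) -> TemplateRegion:
    """Choose the riboprobe template interval for a mapped probeset.

    The smallest interval containing every probe hit is taken and, if
    shorter than ``min_len``, grown toward ``max_len`` with growth
    toward the transcript 3' end first (clipped at transcript bounds).
    Growing to the upper bound rather than the lower one leaves the
    downstream primer search room to place a ``min_len``..``max_len``
    product that still covers the probes; a span already in the
    ``min_len``..``max_len`` range is returned as-is.  If the probe span
    exceeds ``max_len``, the 3'-most ``max_len`` window maximising the
    number of fully contained probes is chosen instead.

    Raises :class:`CoverageError` below ``min_coverage`` and
    :class:`TemplateLengthError` when the transcript is shorter than
    ``min_len``.
    """
    if mapping.coverage_fraction < min_coverage:
        raise CoverageError(
            f"{mapping.probeset_id} on {mapping.transcript_id}: coverage "
            f"{mapping.coverage_fraction:.3f} < {min_coverage}"
        )
    seq = transcripts[mapping.transcript_id]
    length = len(seq)
    if length < min_len:
        raise TemplateLengthError(
            f"{mapping.transcript_id}: length {length} < min template {min_len}"
        )
    span_start, span_end = mapping.span
    span_len = span_end - span_start

    if span_len <= max_len:
        if span_len >= min_len:
            start, end = span_start, span_end
        else:
            end = min(length, span_start + max_len)
            start = max(0, end - max_len)
        covered = {h.probe_index for h in mapping.hits
                   if h.start >= start and h.end <= end}
        return TemplateRegion(mapping.transcript_id, start, end, len(covered),
                              probe_span=(span_start, span_end))

    # Probe span wider than max_len: pick the max_len window with the most
    # fully contained probes, ties to the 3'-most window.  Optimal windows
    # end either at the transcript end or where a probe is about to fall
    # off the 5' edge, so only those ends need evaluating.
    candidate_ends = sorted(
        {min(length, h.start + max_len) for h in mapping.hits} | {length}
    )
    best = None
    for end in candidate_ends:
        if end < max_len:
            continue
        start = end - max_len
        inside = [h for h in mapping.hits if h.start >= start and h.end <= end]
        covered = {h.probe_index for h in inside}
        key = (len(covered), end)
        if (best is None or key > best[0]) and inside:
            span = (min(h.start for h in inside), max(h.end for h in inside))
            best = (key, TemplateRegion(mapping.transcript_id, start, end,
                                        len(covered), probe_span=span))
    if best is None:
        # no window fully contains any probe; fall back to the 3'-most window
        end = length
        best = (None, TemplateRegion(mapping.transcript_id, end - max_len, end, 0))
    return best[1]


def rank_probesets(mappings: Sequence[ProbesetMapping]) -> list[ProbesetMapping]:
    """Order candidate mappings for one locus: coverage descending, then
    3'-most probe-span end descending, then probeset id."""
    if not mappings:
        raise ValueError("no mappings to rank")
    return sorted(
        mappings,
        key=lambda m: (-m.coverage_fraction, -m.span[1], m.probeset_id),
    )


def write_template_bed(
    templates: Sequence[tuple[str, TemplateRegion]], path: str | os.PathLike
) -> None:
    """Write (probeset, template) pairs as transcript-space BED4."""
    with open(path, "w") as fh:
        for pid, region in templates:
            fh.write(
                f"{region.transcript_id}\t{region.start}\t{region.end}\t{pid}\n"
            )
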
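"""Synthetic fixtures with known ground truth, plus the bundled
reference table of published anchor genes.

Two generators emulate the two kinds of input the package consumes:

- an expression fixture shaped like the compartmental microarray data
  the selection cascade was built for: 11 anatomical compartments of the
  E15.5 mouse kidney, a few replicate arrays each, a large background of
  unremarkable probesets at a constant level plus Gaussian noise
  (truncated at zero -- fluorescence cannot go negative), and a handful
  of planted anchor probesets elevated by a known fold in exactly one
  compartment;
- a transcript fixture: random-sequence transcripts with the 11 25-mers
  of each planted probeset copied from known coordinates, 3'-biased the
  way real array probesets are.

Both generators are seed-deterministic, record their ground truth, and
emit files directly readable by the package's I/O functions.  The
background level defaults to 50 RFU -- deliberately below the 100 RFU
raw-signal filter so background probesets are doubly excluded; raise it
to stress the fold filter alone.

:func:`load_anchor_gene_table` returns the bundled reference table of
37 SISH-validated anchor genes (raw signal, fold-change and
median-of-others per probeset across six kidney compartments), kept
exactly as printed in its source, including the varying decimal
precision of the fold-change column.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .probemap import PROBE_LENGTH, OligoProbe, write_transcripts

__all__ = [
    "KIDNEY_COMPARTMENTS",
    "ExpressionFixtureTruth",
    "TranscriptFixtureTruth",
    "default_planted_anchors",
    "generate_expression_fixture",
    "generate_transcript_fixture",
    "write_expression_fixture",
    "write_transcript_fixture",
    "load_anchor_gene_table",
    "anchor_table_stats",
]

#: The 11 profiled compartments of the midgestation kidney: cap
#: mesenchyme, medullary/cortical interstitium, ureteric tip, cortical
#: and medullary collecting duct, renal vesicle, S-shaped body, early
#: proximal tubule, loop of Henle, renal corpuscle.
KIDNEY_COMPARTMENTS = (
    "CM", "MI", "CI", "UT", "CCD", "MCD", "RV", "SSB", "EPT", "LoH", "RC",
)


@dataclass(frozen=True)
class ExpressionFixtureTruth:
    """Ground truth of a generated expression matrix."""

    planted: tuple[tuple[str, str, float], ...]  # (probeset, compartment, fold)
    background_level: float
    noise_sd: float
    seed: int

    def planted_ids(self) -> set[str]:
        return {p for p, _, _ in self.planted}


@dataclass(frozen=True)
class TranscriptFixtureTruth:
    """Ground truth of a generated transcriptome + probe table."""

    transcript_lengths: dict[str, int]
    #: probeset -> (transcript, ((probe_index, start, end, orientation), ...))
    planted_probesets: dict[str, tuple[str, tuple[tuple[int, int, int, str], ...]]]
    probeset_size: int
    seed: int


def default_planted_anchors(
    fold: float = 20.0,
    compartments: Sequence[str] = ("EPT", "UT", "MCD", "RV", "LoH"),
) -> list[tuple[str, str, float]]:
    """Five planted anchors, one per anchor-bearing compartment."""
    return [(f"anchor_{c}", c, fold) for c in compartments]


def generate_expression_fixture(
    n_compartments: int = 11,
    replicates: int = 3,
    n_background: int = 200,
    planted: Sequence[tuple[str, str, float]] | None = None,
    background_level: float = 50.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionFixtureTruth]:
    """Expression matrix + sample table + truth with planted anchors.

    Background probesets draw ``background_level`` plus Gaussian noise
    (sd ``noise_sd``, truncated at 0) in every sample; each planted
    probeset additionally has its level multiplied by ``fold`` in the
    samples of its compartment.  Compartment names are the kidney labels
    (for up to 11 compartments) or generic ``C01..`` beyond that.
    """
    if n_compartments < 2:
        raise ValueError("need at least 2 compartments")
    if replicates < 1 or n_background < 0:
        raise ValueError("invalid replicate or background count")
    if noise_sd < 0 or background_level < 0:
        raise ValueError("background_level and noise_sd must be non-negative")
    if n_compartments <= len(KIDNEY_COMPARTMENTS):
        comps = list(KIDNEY_COMPARTMENTS[:n_compartments])
    else:
        comps = [f"C{i:02d}" for i in range(1, n_compartments + 1)]
    if planted is None:
        planted = [p for p in default_planted_anchors() if p[1] in comps]
    for pid, comp, fold in planted:
        if comp not in comps:
            raise ValueError(f"planted compartment {comp!r} not in fixture")
        if fold < 1:
            raise ValueError(f"planted fold for {pid!r} must be >= 1")

    rng = np.random.default_rng(seed)
    samples = [f"{c}_r{i}" for c in comps for i in range(1, replicates + 1)]
    table = pd.DataFrame(
        {"sample_id": samples, "compartment": [s.rsplit("_r", 1)[0] for s in samples]}
    )

    probesets = [f"bg_{i:04d}" for i in range(1, n_background + 1)]
    means = np.full((n_background, len(samples)), background_level)
    for pid, comp, fold in planted:
        row = np.full(len(samples), background_level)
        for j, s in enumerate(samples):
            if s.rsplit("_r", 1)[0] == comp:
                row[j] = background_level * fold
        probesets.append(pid)
        means = np.vstack([means, row])
    noise = rng.normal(0.0, noise_sd, size=means.shape) if noise_sd > 0 else 0.0
    values = np.clip(means + noise, 0.0, None)
    matrix = pd.DataFrame(values, index=pd.Index(probesets, name="probeset_id"),
                          columns=samples)
    truth = ExpressionFixtureTruth(
        planted=tuple((p, c, float(f)) for p, c, f in planted),
        background_level=float(background_level),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
    return matrix, table, truth


def generate_transcript_fixture(
    n_transcripts: int = 10,
    length_range: tuple[int, int] = (1500, 3000),
    n_probesets: int = 5,
    probes_per_set: int = 11,
    probeset_size: int = 11,
    antisense_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], list[OligoProbe], TranscriptFixtureTruth]:
    """Random transcriptome with planted probesets at known coordinates.

    Each of the first ``n_probesets`` transcripts hosts one probeset:
    ``probes_per_set`` non-overlapping 25-mers copied from a 3'-biased
    window (probe i upstream of probe i+1, separated by small random
    gaps).  With ``antisense_fraction`` > 0 a corresponding share of
    probes is stored reverse-complemented, modelling array probes that
    are antisense to the transcript.  ``probes_per_set`` may be below
    ``probeset_size`` to create under-covered probesets.
    """
    lo, hi = length_range
    if lo < 1000:
        raise ValueError("transcripts must be at least 1000 nt")
    if n_probesets > n_transcripts:
        raise ValueError("more probesets than transcripts to host them")
    if not (1 <= probes_per_set <= probeset_size):
        raise ValueError("need 1 <= probes_per_set <= probeset_size")

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    transcripts: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for i in range(1, n_transcripts + 1):
        tid = f"tx_{i:03d}"
        L = int(rng.integers(lo, hi + 1))
        transcripts[tid] = "".join(rng.choice(alphabet, size=L))
        lengths[tid] = L

    from .primers import reverse_complement

    probes: list[OligoProbe] = []
    planted: dict[str, tuple[str, tuple[tuple[int, int, int, str], ...]]] = {}
    for k in range(1, n_probesets + 1):
        pid = f"ps_{k:03d}"
        tid = f"tx_{k:03d}"
        seq = transcripts[tid]
        L = lengths[tid]
        gaps = rng.integers(2, 8, size=probes_per_set - 1)
        span = probes_per_set * PROBE_LENGTH + int(gaps.sum())
        start0 = L - span - 300  # 3'-biased window, 300 nt short of the end
        if start0 < 0:
            raise ValueError(
                f"transcript {tid} too short to host {probes_per_set} probes"
            )
        coords = []
        pos = start0
        for idx in range(probes_per_set):
            sub = seq[pos : pos + PROBE_LENGTH]
            if rng.random() < antisense_fraction:
                probe_seq, orient = reverse_complement(sub), "antisense"
            else:
                probe_seq, orient = sub, "sense"
            probes.append(OligoProbe(pid, idx, probe_seq))
            coords.append((idx, pos, pos + PROBE_LENGTH, orient))
            pos += PROBE_LENGTH + (int(gaps[idx]) if idx < len(gaps) else 0)
        planted[pid] = (tid, tuple(coords))
    truth = TranscriptFixtureTruth(
        transcript_lengths=lengths,
        planted_probesets=planted,
        probeset_size=probeset_size,
        seed=int(seed),
    )
    return transcripts, probes, truth


def write_expression_fixture(
    out_dir: str | os.PathLike, seed: int = 0, **kwargs
) -> ExpressionFixtureTruth:
    """Generate and write matrix.tsv, samples.tsv and truth.json."""
    matrix, table, truth = generate_expression_fixture(seed=seed, **kwargs)
    os.makedirs(out_dir, exist_ok=True)
    matrix.to_csv(os.path.join(out_dir, "matrix.tsv"), sep="\t",
                  float_format="%.6f")
    table.to_csv(os.path.join(out_dir, "samples.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(asdict(truth), fh, indent=2)
    return truth


def write_transcript_fixture(
    out_dir: str | os.PathLike, seed: int = 0, **kwargs
) -> TranscriptFixtureTruth:
    """Generate and write transcripts.fa, probes.tsv and truth.json."""
    transcripts, probes, truth = generate_transcript_fixture(seed=seed, **kwargs)
    os.makedirs(out_dir, exist_ok=True)
    write_transcripts(transcripts, os.path.join(out_dir, "transcripts.fa"))
    pd.DataFrame(
        {
            "probeset_id": [p.probeset_id for p in probes],
            "probe_index": [p.probe_index for p in probes],
            "sequence": [p.sequence for p in probes],
        }
    ).to_csv(os.path.join(out_dir, "probes.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(
            {
                "transcript_lengths": truth.transcript_lengths,
                "planted_probesets": {
                    pid: {"transcript_id": tid, "probes": list(map(list, coords))}
                    for pid, (tid, coords) in truth.planted_probesets.items()
                },
                "probeset_size": truth.probeset_size,
                "seed": truth.seed,
            },
            fh,
            indent=2,
        )
    return truth


def load_anchor_gene_table() -> pd.DataFrame:
    """The bundled 37-row reference table of SISH-validated anchor genes.

    Columns: probeset_id, gene_symbol, compartment, raw, fold_change,
    median_other (floats) plus ``fold_change_printed`` preserving the
    value exactly as printed (the source rounds some fold-changes to
    integers, others to one decimal).
    """
    ref = resources.files("anchorprobe").joinpath("data/anchor_genes.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    out = pd.DataFrame(
        {
            "probeset_id": df["probeset_id"],
            "gene_symbol": df["gene_symbol"],
            "compartment": df["compartment"],
            "raw": df["raw"].astype(float),
            "fold_change": df["fold_change"].astype(float),
            "fold_change_printed": df["fold_change"],
            "median_other": df["median_other"].astype(float),
        }
    )
    return out


def anchor_table_stats(q: float = 0.0) -> pd.DataFrame:
    """The reference table reshaped as a statistics table.

    The source table carries no p-values (its rows are all significant
    survivors of the cascade), so ``p_anova`` and ``q_bh`` are set to
    ``q``, below threshold by default.
    """
    table = load_anchor_gene_table()
    fc = table["fold_change"].to_numpy()
    return pd.DataFrame(
        {
            "probeset_id": table["probeset_id"],
            "compartment": table["compartment"],
            "raw": table["raw"],
            "median_other": table["median_other"],
            "fold_change": fc,
            "log2_fold_change": np.log2(fc),
            "p_anova": q,
            "q_bh": q,
        }
    )
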
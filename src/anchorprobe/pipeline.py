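"""End-to-end orchestration: selection -> mapping -> design -> in-silico PCR.

:func:`run_end_to_end` wires the stages together from a single
:class:`RunConfig`, writes a machine-readable JSON run report whether or
not it succeeds, and reports per-stage counts and failure reasons.
Every threshold actually applied is logged so a run is auditable from
its log alone.

Exit codes: 0 success, 2 input/validation error, 3 stage failure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import expression, patterns, probemap, primers, selection
from .errors import AnchorProbeError, ConsistencyError, FormatError

__all__ = ["RunConfig", "run_end_to_end", "EXIT_OK", "EXIT_INVALID", "EXIT_STAGE"]

logger = logging.getLogger("anchorprobe")

EXIT_OK = 0
EXIT_INVALID = 2
EXIT_STAGE = 3


@dataclass
class RunConfig:
    """Paths and parameters for a full run.

    ``annotations`` is optional; when given, SISH pattern classification
    runs after selection.  ``probes``/``transcripts`` are required for
    the riboprobe-design stages.
    """

    matrix: str
    samples: str
    probes: str
    transcripts: str
    out_dir: str
    annotations: str | None = None
    selection: selection.SelectionConfig = field(
        default_factory=selection.SelectionConfig
    )
    constraints: primers.PrimerConstraints = field(
        default_factory=primers.PrimerConstraints
    )
    allow_antisense: bool = True
    max_product: int = 5000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sel = selection.SelectionConfig(**raw.pop("selection", {}))
        cons = primers.PrimerConstraints(**raw.pop("constraints", {}))
        return cls(selection=sel, constraints=cons, **raw)

    def validate(self) -> None:
        for name in ("matrix", "samples", "probes", "transcripts"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path}")
        if self.annotations and not os.path.exists(self.annotations):
            raise FileNotFoundError(f"annotations file not found: {self.annotations}")


def _design_for_candidates(
    candidate_ids: list[str], cfg: RunConfig, report: dict
) -> None:
    probes = probemap.read_probes(cfg.probes)
    transcripts = probemap.read_transcripts(cfg.transcripts)
    sizes: dict[str, int] = {}
    for p in probes:
        sizes[p.probeset_id] = sizes.get(p.probeset_id, 0) + 1
    wanted = [p for p in probes if p.probeset_id in set(candidate_ids)]
    report["stages"]["probe_mapping"] = {"probes_searched": len(wanted)}
    hits = probemap.map_probes(wanted, transcripts, cfg.allow_antisense)
    mappings = probemap.build_mappings(hits, sizes)
    by_probeset: dict[str, list[probemap.ProbesetMapping]] = {}
    for m in mappings:
        by_probeset.setdefault(m.probeset_id, []).append(m)

    designs = []
    failures = []
    templates = []
    for pid in candidate_ids:
        if pid not in by_probeset:
            failures.append({"probeset_id": pid, "stage": "probe_mapping",
                             "reason": "no transcript hit"})
            continue
        best = probemap.rank_probesets(by_probeset[pid])[0]
        try:
            region = probemap.select_template(transcripts, best)
            pair = primers.design_primers(
                transcripts[best.transcript_id], region, cfg.constraints
            )
            amplicons = primers.insilico_pcr(pair, transcripts, cfg.max_product)
        except AnchorProbeError as exc:
            failures.append({"probeset_id": pid, "stage": type(exc).__name__,
                             "reason": str(exc)})
            continue
        templates.append((pid, region))
        designs.append(
            {
                "probeset_id": pid,
                "transcript_id": best.transcript_id,
                "coverage_fraction": best.coverage_fraction,
                "template_start": region.start,
                "template_end": region.end,
                "forward_seq": pair.forward_seq,
                "reverse_tagged_seq": pair.reverse_tagged_seq,
                "forward_tm": pair.forward_tm,
                "reverse_tm": pair.reverse_tm,
                "product_length": pair.product_length,
                "amplicon_count": len(amplicons),
                "unique_product": len(amplicons) == 1,
            }
        )
    report["stages"]["design"] = {
        "designed": len(designs),
        "failed": len(failures),
    }
    report["designs"] = designs
    report["failures"].extend(failures)
    out = cfg.out_dir
    if designs:
        import pandas as pd

        pd.DataFrame(designs).to_csv(
            os.path.join(out, "primer_designs.tsv"), sep="\t", index=False
        )
        probemap.write_template_bed(templates, os.path.join(out, "templates.bed"))


def run_end_to_end(cfg: RunConfig) -> tuple[int, dict]:
    """Run the whole pipeline; always writes ``run_report.json``.

    Returns ``(exit_code, report)``.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {"stages": {}, "failures": [], "seed": cfg.seed}
    code = EXIT_OK
    try:
        cfg.validate()
        logger.info(
            "selection thresholds: q<%g fold>=%g raw>%g cross>=%g median_max=%g "
            "overrides=%s",
            cfg.selection.p_threshold, cfg.selection.fold_min,
            cfg.selection.raw_min, cfg.selection.cross_fold_exclude,
            cfg.selection.median_max, cfg.selection.per_compartment_fold_min,
        )
        matrix, table = expression.read_matrix(cfg.matrix, cfg.samples)
        report["stages"]["expression_io"] = {
            "probesets": int(matrix.shape[0]),
            "samples": int(matrix.shape[1]),
        }
        candidates = selection.select_candidates(matrix, table, cfg.selection)
        counts = selection.write_candidates(candidates, cfg.out_dir)
        report["stages"]["selection"] = {"candidates_per_compartment": counts}

        if cfg.annotations:
            anns = patterns.read_annotations(cfg.annotations)
            summary = patterns.write_labels(anns, cfg.out_dir)
            report["stages"]["classification"] = summary

        candidate_ids = [
            pid
            for comp_df in candidates.values()
            for pid in comp_df["probeset_id"].tolist()
        ]
        _design_for_candidates(candidate_ids, cfg, report)
    except (FormatError, ConsistencyError, FileNotFoundError, ValueError) as exc:
        report["error"] = {"stage": "validation", "message": str(exc)}
        code = EXIT_INVALID
    except AnchorProbeError as exc:
        report["error"] = {"stage": type(exc).__name__, "message": str(exc)}
        code = EXIT_STAGE

    report["exit_code"] = code
    with open(os.path.join(cfg.out_dir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return code, report
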
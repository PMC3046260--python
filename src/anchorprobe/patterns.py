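"""Classification of section in situ hybridisation (SISH) outcomes.

Each validated gene carries a per-compartment annotation of whether
signal was detected, plus the compartment the microarray analysis
predicted it to mark.  Genes fall into five categories:

- ``specific``: detected in the target compartment only -- a validated
  anchor gene;
- ``enriched``: detected in the target and at least one (but not every)
  other compartment -- a marker gene;
- ``ubiquitous``: detected in every annotated compartment;
- ``not_detected``: no detectable signal anywhere;
- ``non_specific``: signal somewhere, but not in the target.

Graded annotations (weak / present / strong) collapse to "detected" for
classification; the grade is carried through for reporting only.  The
classifier never infers compartments that were not annotated: a gene
also expressed in an unprofiled structure must be encoded by the caller
as an extra compartment key.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LABELS",
    "DETECTED_CALLS",
    "SishAnnotation",
    "classify_pattern",
    "validation_summary",
    "read_annotations",
    "write_labels",
]

LABELS = ("specific", "enriched", "ubiquitous", "not_detected", "non_specific")

#: Call values that count as detection; anything else must be "not_detected".
DETECTED_CALLS = frozenset({"detected", "weak", "present", "strong"})
_VALID_CALLS = DETECTED_CALLS | {"not_detected"}


@dataclass(frozen=True)
class SishAnnotation:
    """Per-gene SISH result: the predicted target compartment and a call
    for every annotated compartment."""

    gene_id: str
    target_compartment: str
    calls: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.calls:
            raise ValueError(f"{self.gene_id}: empty call map")
        if self.target_compartment not in self.calls:
            raise ValueError(
                f"{self.gene_id}: target {self.target_compartment!r} missing from calls"
            )
        bad = {c for c in self.calls.values() if c not in _VALID_CALLS}
        if bad:
            raise ValueError(f"{self.gene_id}: unknown calls {sorted(bad)}")

    def detected_in(self) -> frozenset[str]:
        return frozenset(
            c for c, call in self.calls.items() if call in DETECTED_CALLS
        )


def classify_pattern(annotation: SishAnnotation) -> str:
    """Assign one of the five validation categories (see module docs)."""
    detected = annotation.detected_in()
    target = annotation.target_compartment
    if not detected:
        return "not_detected"
    if target not in detected:
        return "non_specific"
    if detected == {target}:
        return "specific"
    if detected == set(annotation.calls):
        return "ubiquitous"
    return "enriched"


def validation_summary(labels: Sequence[str]) -> dict:
    """Counts and percentages per category, plus the combined
    specific+enriched validation rate.

    Percentages are ``100 * count / total`` reported to one decimal.
    """
    if len(labels) == 0:
        raise ValueError("no labels to summarise")
    unknown = set(labels) - set(LABELS)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    total = len(labels)
    counts = {lab: sum(1 for x in labels if x == lab) for lab in LABELS}
    percentages = {lab: round(100.0 * n / total, 1) for lab, n in counts.items()}
    combined = counts["specific"] + counts["enriched"]
    return {
        "total": total,
        "counts": counts,
        "percentages": percentages,
        "combined_validated": combined,
        "combined_validated_pct": round(100.0 * combined / total, 1),
    }


def read_annotations(path: str | os.PathLike) -> list[SishAnnotation]:
    """Read an annotation TSV: gene_id, target_compartment, then one call
    column per compartment."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["gene_id", "target_compartment"]
    if list(df.columns[:2]) != fixed:
        raise ValueError(f"annotation file must start with columns {fixed}")
    comps = list(df.columns[2:])
    if not comps:
        raise ValueError("annotation file has no compartment columns")
    return [
        SishAnnotation(
            gene_id=row["gene_id"],
            target_compartment=row["target_compartment"],
            calls={c: row[c] for c in comps},
        )
        for _, row in df.iterrows()
    ]


def write_labels(
    annotations: Iterable[SishAnnotation],
    out_dir: str | os.PathLike,
) -> dict:
    """Classify annotations, writing a label TSV and a JSON summary.

    Returns the summary dict.
    """
    os.makedirs(out_dir, exist_ok=True)
    anns = list(annotations)
    labels = [classify_pattern(a) for a in anns]
    pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in anns],
            "target_compartment": [a.target_compartment for a in anns],
            "label": labels,
        }
    ).to_csv(os.path.join(out_dir, "pattern_labels.tsv"), sep="\t", index=False)
    summary = validation_summary(labels)
    with open(os.path.join(out_dir, "validation_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
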
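"""The candidate-anchor selection cascade.

An anchor gene is one whose expression is restricted to a single
anatomical compartment.  Candidates are found by a filter cascade over
the per-probeset statistics:

1. differential expression: BH-adjusted Welch-ANOVA q-value below the
   significance threshold (default 0.01);
2. up-regulation: fold-change against the median of the other
   compartments of at least ``fold_min`` (default 2; individual
   compartments may carry a stricter override, e.g. a 10-fold minimum
   for the anchor-rich early proximal tubule);
3. absolute signal: raw mean intensity strictly above ``raw_min``
   (default 100 RFU), keeping candidates above array background;
4. restriction: any probeset at or above ``cross_fold_exclude`` fold in
   a *different* compartment is discarded from every list;
5. ranking: candidates are ordered by ascending median-of-others, ties
   by descending raw signal.  ``median_max`` (default 200 RFU) is a
   ranking preference, not a hard filter: candidates whose
   median-of-others meets or exceeds it sink below all others and are
   flagged, because published anchor sets contain such genes.

Fold thresholds are read as "a minimum of N-fold", i.e. inclusive
(fold >= N passes); the raw-signal threshold is exclusive (raw > 100).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
import yaml

from . import stats as _stats
from .expression import aggregate_by_compartment, compartment_order

__all__ = [
    "SelectionConfig",
    "apply_filters",
    "exclude_cross_expressed",
    "rank_candidates",
    "select_candidates",
    "write_candidates",
]


@dataclass
class SelectionConfig:
    """Thresholds of the selection cascade.

    per_compartment_fold_min maps compartment labels to stricter fold
    minima; any override must be at least ``fold_min``.
    """

    p_threshold: float = 0.01
    fold_min: float = 2.0
    raw_min: float = 100.0
    median_max: float = 200.0
    cross_fold_exclude: float = 2.0
    per_compartment_fold_min: dict[str, float] = field(
        default_factory=lambda: {"EPT": 10.0}
    )

    def __post_init__(self) -> None:
        for name in ("p_threshold", "fold_min", "raw_min", "median_max",
                     "cross_fold_exclude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fold_min < 1:
            raise ValueError("fold_min must be >= 1")
        for comp, f in self.per_compartment_fold_min.items():
            if f < self.fold_min:
                raise ValueError(
                    f"override for {comp!r} ({f}) is below fold_min ({self.fold_min})"
                )

    def effective_fold_min(self, compartment: str) -> float:
        return self.per_compartment_fold_min.get(compartment, self.fold_min)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SelectionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("selection config must be a mapping")
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "p_threshold": self.p_threshold,
                    "fold_min": self.fold_min,
                    "raw_min": self.raw_min,
                    "median_max": self.median_max,
                    "cross_fold_exclude": self.cross_fold_exclude,
                    "per_compartment_fold_min": dict(self.per_compartment_fold_min),
                },
                fh,
                sort_keys=False,
            )


def apply_filters(
    stats: pd.DataFrame, cfg: SelectionConfig | None = None
) -> pd.DataFrame:
    """Significance, fold and raw-signal filters over a stats table.

    Retains rows with ``q_bh < p_threshold``, ``fold_change`` at or above
    the compartment's effective fold minimum, and ``raw`` strictly above
    ``raw_min``.  An empty result is legitimate.
    """
    cfg = cfg or SelectionConfig()
    eff = stats["compartment"].map(cfg.effective_fold_min)
    mask = (
        (stats["q_bh"] < cfg.p_threshold)
        & (stats["fold_change"] >= eff)
        & (stats["raw"] > cfg.raw_min)
    )
    return stats.loc[mask].reset_index(drop=True)


def exclude_cross_expressed(
    candidates: pd.DataFrame,
    profile: pd.DataFrame,
    cfg: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Drop candidates up-regulated in a compartment other than their own.

    A probeset whose fold-change, computed with any non-target
    compartment as target, reaches ``cross_fold_exclude`` is not
    restricted to one compartment and is removed from every list.
    """
    cfg = cfg or SelectionConfig()
    if candidates.empty:
        return candidates.copy()
    folds = _stats.fold_change_profile(profile)
    keep = []
    for _, row in candidates.iterrows():
        other = folds.loc[row["probeset_id"], folds.columns != row["compartment"]]
        keep.append(bool((other < cfg.cross_fold_exclude).all()))
    return candidates.loc[keep].reset_index(drop=True)


def rank_candidates(
    candidates: pd.DataFrame, cfg: SelectionConfig | None = None
) -> pd.DataFrame:
    """Rank one compartment's candidates.

    Ascending median-of-others (quieter background ranks higher), ties
    by descending raw signal, then probeset id.  Candidates whose
    median-of-others meets ``median_max`` are flagged ``high_median`` and
    sink below all unflagged ones.  Ranks run 1..n.
    """
    cfg = cfg or SelectionConfig()
    if candidates["compartment"].nunique() > 1:
        raise ValueError("rank_candidates expects candidates of one compartment")
    out = candidates.copy()
    out["high_median"] = out["median_other"] >= cfg.median_max
    out = out.sort_values(
        by=["high_median", "median_other", "raw", "probeset_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out


def select_candidates(
    matrix: pd.DataFrame,
    table: pd.DataFrame,
    cfg: SelectionConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Full cascade: aggregate, test, filter, exclude, rank.

    Returns one ranked candidate table per compartment (possibly empty),
    keyed by compartment in sample-table order.
    """
    cfg = cfg or SelectionConfig()
    stats = _stats.compute_stats(matrix, table)
    profile = aggregate_by_compartment(matrix, table)
    filtered = apply_filters(stats, cfg)
    restricted = exclude_cross_expressed(filtered, profile, cfg)
    result: dict[str, pd.DataFrame] = {}
    for comp in compartment_order(table):
        sub = restricted.loc[restricted["compartment"] == comp]
        result[comp] = rank_candidates(sub.reset_index(drop=True), cfg)
    return result


def write_candidates(
    candidates: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike
) -> dict[str, int]:
    """Write per-compartment candidate TSVs plus a JSON count summary.

    Returns the ``{compartment: count}`` summary that was written.
    """
    os.makedirs(out_dir, exist_ok=True)
    summary = {comp: int(len(df)) for comp, df in candidates.items()}
    for comp, df in candidates.items():
        df.to_csv(
            os.path.join(out_dir, f"candidates_{comp}.tsv"), sep="\t", index=False
        )
    with open(os.path.join(out_dir, "candidate_counts.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
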
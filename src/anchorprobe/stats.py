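"""Per-probeset compartment-specificity statistics.

For a candidate compartment the relevant quantities are: the mean raw
signal in that compartment (``raw``), the median of the mean signals of
every *other* compartment (``median_other``), their linear ratio
(``fold_change``), a Welch (heteroscedastic) one-way ANOVA p-value over
the replicate groups of all compartments, and its Benjamini-Hochberg
adjusted q-value across probesets.

Fold-change is deliberately the linear ratio ``raw / median_other`` --
that is the arithmetic the published anchor-gene tables follow -- with
``log2_fold_change`` available as an optional report column.

Welch's ANOVA weights each group by ``n_i / s_i**2`` so that unequal
replicate variances between compartments (ubiquitous on raw-scale
microarray data) do not inflate the F statistic.  Zero-variance groups
make the weights undefined; :func:`welch_anova` refuses them rather than
silently adding jitter.  Pipelines over noiseless synthetic data can use
:func:`welch_anova_pvalue_safe`, which resolves the all-groups-constant
case by inspection of the group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.oneway import anova_oneway

from .errors import DegenerateGroupError

__all__ = [
    "WelchAnovaResult",
    "median_other",
    "fold_change",
    "welch_anova",
    "welch_anova_pvalue_safe",
    "bh_adjust",
    "compute_stats",
    "fold_change_profile",
    "STATS_COLUMNS",
]

#: Column layout of the long-format statistics table.
STATS_COLUMNS = [
    "probeset_id",
    "compartment",
    "raw",
    "median_other",
    "fold_change",
    "log2_fold_change",
    "p_anova",
    "q_bh",
]


@dataclass(frozen=True)
class WelchAnovaResult:
    """Welch heteroscedastic one-way ANOVA: F statistic, numerator and
    denominator degrees of freedom, and upper-tail p-value."""

    F: float
    df1: float
    df2: float
    p: float


def median_other(profile: pd.DataFrame, probeset: str, target: str) -> float:
    """Median of the compartment means of ``probeset`` excluding ``target``.

    ``profile`` is a probeset x compartment frame as produced by
    :func:`anchorprobe.expression.aggregate_by_compartment`.  With an
    even number of remaining compartments the mean of the two central
    values is returned (standard median).
    """
    if probeset not in profile.index:
        raise KeyError(f"unknown probeset {probeset!r}")
    if target not in profile.columns:
        raise KeyError(f"unknown compartment {target!r}")
    if profile.shape[1] < 2:
        raise ValueError("need at least 2 compartments to take a median of others")
    others = profile.loc[probeset, profile.columns != target]
    return float(np.median(others.to_numpy(dtype=float)))


def fold_change(raw: float, median_other: float) -> float:
    """Linear fold-change ``raw / median_other``.

    A positive signal against a zero median is reported as ``inf``; the
    doubly-degenerate 0/0 case is defined as 1 (no change).
    """
    if raw < 0 or median_other < 0:
        raise ValueError("signal intensities must be non-negative")
    if median_other == 0:
        return 1.0 if raw == 0 else float("inf")
    return raw / median_other


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    return [np.asarray(g, dtype=float) for g in groups]


def welch_anova(groups: Sequence[Sequence[float]]) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA over replicate groups.

    Each group needs >=2 values and positive variance.  The F statistic,
    Satterthwaite-type denominator degrees of freedom and upper-tail
    p-value follow the standard Welch construction (as implemented by
    statsmodels' ``anova_oneway`` with unequal variances and Welch
    correction).
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if np.var(g, ddof=1) <= 0:
            raise DegenerateGroupError(
                f"group {i} has zero variance; Welch weights are undefined"
            )
    res = anova_oneway(gs, use_var="unequal", welch_correction=True)
    return WelchAnovaResult(
        F=float(res.statistic),
        df1=float(res.df_num),
        df2=float(res.df_denom),
        p=float(res.pvalue),
    )


def welch_anova_pvalue_safe(groups: Sequence[Sequence[float]]) -> float:
    """Welch ANOVA p-value with a defined answer for noiseless data.

    When *every* group is constant the hypothesis test degenerates to an
    exact comparison of means: p = 0 if any two group means differ,
    p = 1 otherwise.  A mix of constant and varying groups is still an
    error -- it cannot arise under any continuous noise model and almost
    surely indicates corrupted input.
    """
    gs = _as_groups(groups)
    variances = [np.var(g, ddof=1) if g.size > 1 else 0.0 for g in gs]
    if all(v == 0 for v in variances):
        means = [float(np.mean(g)) for g in gs]
        return 0.0 if (max(means) - min(means)) > 0 else 1.0
    if any(v == 0 for v in variances):
        raise DegenerateGroupError(
            "mixed zero- and positive-variance groups; cannot form Welch weights"
        )
    return welch_anova(gs).p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j>=i} (p_(j) * n / j)`` over the sorted p-values,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_profile(profile: pd.DataFrame) -> pd.DataFrame:
    """Fold-change of every probeset against every compartment as target.

    Returns a probeset x compartment frame where entry (p, c) is the
    mean signal of p in c divided by the median of p's means over the
    other compartments.  Used both for the target compartment's own
    fold-change and for the cross-compartment exclusion rule.
    """
    values = profile.to_numpy(dtype=float)
    n_comp = values.shape[1]
    if n_comp < 2:
        raise ValueError("need at least 2 compartments")
    folds = np.empty_like(values)
    for j in range(n_comp):
        med = np.median(np.delete(values, j, axis=1), axis=1)
        raw = values[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(med > 0, raw / np.where(med > 0, med, 1.0), np.inf)
        f = np.where((med == 0) & (raw == 0), 1.0, f)
        folds[:, j] = f
    return pd.DataFrame(folds, index=profile.index, columns=profile.columns)


def compute_stats(matrix: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Long-format specificity statistics for every (probeset, compartment).

    One Welch ANOVA p-value is computed per probeset over its replicate
    groups (all compartments) and BH-adjusted across probesets; raw,
    median-of-others and fold-change are computed per candidate target
    compartment.  Returns a DataFrame with :data:`STATS_COLUMNS`.
    """
    from .expression import aggregate_by_compartment, compartment_order

    profile = aggregate_by_compartment(matrix, table)
    order = compartment_order(table)
    comp_of = dict(
        zip(table["sample_id"].astype(str), table["compartment"].astype(str))
    )
    group_cols = {c: [s for s in matrix.columns if comp_of[s] == c] for c in order}

    pvals = np.empty(matrix.shape[0])
    data = matrix.to_numpy(dtype=float)
    col_idx = {s: i for i, s in enumerate(matrix.columns)}
    group_idx = [np.array([col_idx[s] for s in group_cols[c]]) for c in order]
    for i in range(data.shape[0]):
        groups = [data[i, idx] for idx in group_idx]
        pvals[i] = welch_anova_pvalue_safe(groups)
    qvals = bh_adjust(pvals)

    folds = fold_change_profile(profile)
    rows = []
    values = profile.to_numpy(dtype=float)
    for j, comp in enumerate(order):
        med = np.median(np.delete(values, j, axis=1), axis=1)
        for i, pid in enumerate(profile.index):
            fc = folds.iat[i, j]
            rows.append(
                (
                    pid,
                    comp,
                    values[i, j],
                    med[i],
                    fc,
                    np.log2(fc) if fc > 0 else -np.inf,
                    pvals[i],
                    qvals[i],
                )
            )
    return pd.DataFrame(rows, columns=STATS_COLUMNS)
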
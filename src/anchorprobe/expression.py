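"""Expression-matrix and sample-table I/O plus compartment aggregation.

The starting material for anchor-gene selection is a probeset x sample
matrix of raw microarray fluorescence (RFU) together with a map from
each sample (one hybridised array) to the anatomical compartment it was
dissected from.  Replicate arrays of a compartment are summarised by
their arithmetic mean into a probeset x compartment profile; all
downstream statistics operate on that profile plus the per-sample
replicate values.

File formats
------------
Matrix: UTF-8 TSV, header ``probeset_id\\t<sample ids...>``, one row per
probeset, non-negative reals.
Sample table: UTF-8 TSV with header ``sample_id\\tcompartment``.

Compartments keep the order in which they first appear in the sample
table, so reports follow the user's layout rather than an alphabetical
one.  Missing values are not permitted; impute upstream if needed.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

__all__ = [
    "read_matrix",
    "read_sample_table",
    "validate_matrix",
    "validate_sample_table",
    "aggregate_by_compartment",
    "compartment_order",
    "write_profile",
    "read_profile",
]


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample table (columns ``sample_id``, ``compartment``).

    Sample ids must be unique and no label may be empty.  Returns the
    table unchanged so calls can be chained.
    """
    required = {"sample_id", "compartment"}
    if not required.issubset(table.columns):
        raise FormatError(
            f"sample table needs columns {sorted(required)}, got {list(table.columns)}"
        )
    if table.empty:
        raise FormatError("sample table is empty")
    if table[["sample_id", "compartment"]].isna().any().any():
        raise FormatError("missing sample or compartment label")
    sids = table["sample_id"].astype(str)
    comps = table["compartment"].astype(str)
    if sids.duplicated().any():
        dups = sorted(sids[sids.duplicated()].unique())
        raise FormatError(f"duplicate sample ids: {dups}")
    if (sids.str.len() == 0).any() or (comps.str.len() == 0).any():
        raise FormatError("empty sample or compartment label")
    return table


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate an expression matrix (index = probesets, columns = samples)."""
    if matrix.index.duplicated().any():
        dups = sorted(matrix.index[matrix.index.duplicated()].unique())
        raise FormatError(f"duplicate probeset ids: {dups}")
    if matrix.columns.duplicated().any():
        dups = sorted(matrix.columns[matrix.columns.duplicated()].unique())
        raise FormatError(f"duplicate sample ids in matrix: {dups}")
    if matrix.empty:
        raise FormatError("expression matrix has no rows or no columns")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("expression matrix contains non-numeric entries")
    if np.isnan(values).any():
        raise FormatError("expression matrix contains missing values")
    if (values < 0).any():
        bad = matrix.index[(values < 0).any(axis=1)][0]
        raise ValueError(f"negative signal intensity in probeset {bad!r}")
    return matrix


def _check_consistency(matrix: pd.DataFrame, table: pd.DataFrame) -> None:
    known = set(table["sample_id"].astype(str))
    missing = [s for s in matrix.columns if s not in known]
    if missing:
        raise ConsistencyError(
            f"matrix samples absent from sample table: {missing}"
        )


def read_sample_table(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_table(table)


def read_matrix(
    path: str | os.PathLike, sample_table_path: str | os.PathLike
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate an expression matrix and its sample table.

    Returns ``(matrix, sample_table)`` where the matrix is indexed by
    probeset id with one column per sample.  Every sample in the matrix
    must be declared in the sample table.
    """
    table = read_sample_table(sample_table_path)
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse expression matrix: {exc}") from exc
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    validate_matrix(matrix)
    _check_consistency(matrix, table)
    return matrix, table


def compartment_order(table: pd.DataFrame) -> list[str]:
    """Compartments in order of first appearance in the sample table."""
    return list(dict.fromkeys(table["compartment"].astype(str)))


def aggregate_by_compartment(
    matrix: pd.DataFrame, table: pd.DataFrame
) -> pd.DataFrame:
    """Mean replicate signal per (probeset, compartment).

    Returns a probeset x compartment DataFrame; compartment columns keep
    first-appearance order from the sample table.  Samples listed in the
    table but absent from the matrix are ignored, but a compartment with
    no samples left in the matrix is an error.
    """
    validate_sample_table(table)
    validate_matrix(matrix)
    _check_consistency(matrix, table)
    comp_of = dict(
        zip(table["sample_id"].astype(str), table["compartment"].astype(str))
    )
    order = compartment_order(table)
    cols: dict[str, list[str]] = {c: [] for c in order}
    for s in matrix.columns:
        cols[comp_of[s]].append(s)
    empty = [c for c in order if not cols[c]]
    if empty:
        raise ConsistencyError(f"compartments with no samples in matrix: {empty}")
    profile = pd.DataFrame(
        {c: matrix[cols[c]].mean(axis=1) for c in order}, index=matrix.index
    )
    profile.columns.name = "compartment"
    profile.index.name = matrix.index.name or "probeset_id"
    return profile


def write_profile(profile: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a compartment profile as TSV with full float precision."""
    profile.to_csv(path, sep="\t", float_format="%.17g")


def read_profile(path: str | os.PathLike) -> pd.DataFrame:
    profile = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    profile.index = profile.index.astype(str)
    profile.columns.name = "compartment"
    return profile
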
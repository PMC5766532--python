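"""CSV input/output for abundance matrices and group labels.

Layout convention: header row of metabolite names, first column of sample
IDs, samples in rows. A ``transpose`` flag accommodates exports with
metabolites in rows.
"""

from __future__ import annotations

import csv
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import AbundanceMatrix, GroupLabels

__all__ = [
    "DEFAULT_MISSING_TOKENS",
    "read_matrix",
    "write_matrix",
    "read_groups",
    "write_groups",
]

DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN"})


def read_matrix(
    path: str | PathLike,
    missing_tokens: frozenset[str] | set[str] = DEFAULT_MISSING_TOKENS,
    zeros_as_missing: bool = False,
    transpose: bool = False,
) -> AbundanceMatrix:
    """Load an abundance matrix from CSV.

    Cells matching ``missing_tokens`` (after stripping whitespace) become
    missing; with ``zeros_as_missing`` exact zeros are treated as missing
    too. Any other non-numeric cell raises a ``ValueError`` naming the
    offending row and column.
    """
    tokens = {t.strip() for t in missing_tokens}
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if transpose:
        df = df.T

    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip()
            if cell in tokens:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at sample {df.index[i]!r}, "
                    f"metabolite {df.columns[j]!r} in {path}"
                ) from None
    if zeros_as_missing:
        values[values == 0.0] = np.nan
    with np.errstate(invalid="ignore"):
        neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative abundance {values[i, j]} at sample {df.index[i]!r}, "
            f"metabolite {df.columns[j]!r}; abundances must be non-negative"
        )
    return AbundanceMatrix(values, list(df.index), list(df.columns))


def write_matrix(
    matrix: AbundanceMatrix,
    path: str | PathLike,
    allow_missing: bool = False,
    missing_token: str = "NA",
) -> None:
    """Write a matrix to CSV with full float precision.

    Missing entries are rejected unless ``allow_missing`` is set, in which
    case they are written as ``missing_token``.
    """
    if matrix.n_missing and not allow_missing:
        raise ValueError(
            f"matrix has {matrix.n_missing} missing entries; "
            "pass allow_missing=True to write them as NA"
        )
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", *matrix.metabolite_ids])
        for sid, row in zip(matrix.sample_ids, matrix.values):
            cells = [
                missing_token if np.isnan(v) else repr(float(v)) for v in row
            ]
            writer.writerow([sid, *cells])


def read_groups(path: str | PathLike, matrix: AbundanceMatrix) -> GroupLabels:
    """Load two-class labels from a two-column CSV and align to matrix rows.

    The file must have a header and cover every sample in ``matrix``; labels
    are returned in the matrix's sample order.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("group file needs two columns: sample ID, label")
    mapping = dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))
    missing = [s for s in matrix.sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"samples absent from group file: {missing}")
    labels = np.array([mapping[s] for s in matrix.sample_ids])
    return GroupLabels(labels)


def write_groups(
    groups: GroupLabels, matrix: AbundanceMatrix, path: str | PathLike
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "group"])
        for sid, lab in zip(matrix.sample_ids, groups.labels):
            writer.writerow([sid, lab])
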
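"""Core containers shared across the package.

Abundance matrices are stored as dense float arrays with NaN marking
missing entries; samples are rows, metabolites are columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "GroupLabels",
    "MissingDataset",
    "MethodResult",
    "FilterResult",
]


@dataclass
class AbundanceMatrix:
    """A samples x metabolites abundance table.

    Parameters
    ----------
    values
        2-D float array; NaN encodes a missing measurement. Non-missing
        values must be finite. Raw abundances are non-negative — enforced
        when loading from file — but derived matrices (e.g. standardized
        or SVD-imputed) may carry negative entries.
    sample_ids, metabolite_ids
        Unique row / column identifiers.
    """

    values: np.ndarray
    sample_ids: list[str]
    metabolite_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.metabolite_ids = [str(m) for m in self.metabolite_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{n} rows but {len(self.sample_ids)} sample IDs"
            )
        if p != len(self.metabolite_ids):
            raise ValueError(
                f"{p} columns but {len(self.metabolite_ids)} metabolite IDs"
            )
        for name, ids in (("sample", self.sample_ids),
                          ("metabolite", self.metabolite_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} IDs: {dupes}")
        finite_ok = np.isnan(self.values) | np.isfinite(self.values)
        if not finite_ok.all():
            raise ValueError("non-missing values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean array, True where the entry is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(), list(self.sample_ids), list(self.metabolite_ids)
        )

    def with_values(self, values: np.ndarray) -> "AbundanceMatrix":
        """New matrix sharing this one's IDs."""
        return AbundanceMatrix(
            np.asarray(values, dtype=float),
            list(self.sample_ids),
            list(self.metabolite_ids),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.metabolite_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        return cls(
            df.to_numpy(dtype=float),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
        )


@dataclass
class GroupLabels:
    """Two-class phenotype labels aligned with an AbundanceMatrix's rows."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        uniq = np.unique(self.labels)
        if len(uniq) != 2:
            raise ValueError(
                f"exactly two groups are required, found {len(uniq)}: "
                f"{list(uniq)}"
            )

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def indicator(self) -> np.ndarray:
        """0/1 encoding against the sorted class order."""
        return (self.labels == self.classes[1]).astype(float)

    def group_indices(self) -> dict[Any, np.ndarray]:
        return {c: np.flatnonzero(self.labels == c) for c in self.classes}

    def require_min_group_size(self, n: int) -> None:
        for c, idx in self.group_indices().items():
            if len(idx) < n:
                raise ValueError(
                    f"group {c!r} has {len(idx)} samples, need at least {n}"
                )

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class MissingDataset:
    """A complete matrix, a missingness mask, and the masked observation.

    ``observed`` is NaN exactly where ``mask`` is True; ``complete`` keeps the
    ground truth so imputations can be scored.
    """

    complete: AbundanceMatrix
    mask: np.ndarray
    observed: AbundanceMatrix
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.complete.shape:
            raise ValueError("mask shape does not match the matrix")
        if self.observed.shape != self.complete.shape:
            raise ValueError("observed shape does not match the matrix")
        if self.complete.n_missing:
            raise ValueError("complete matrix must have no missing entries")
        if not np.array_equal(self.observed.missing_mask, self.mask):
            raise ValueError("observed must be missing exactly on the mask")


@dataclass
class MethodResult:
    """A completed matrix tagged with the method that produced it."""

    imputed: AbundanceMatrix
    method: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.imputed.n_missing:
            raise ValueError("imputed matrix still contains missing entries")


@dataclass
class FilterResult:
    """Outcome of missing-variable filtering."""

    filtered: AbundanceMatrix
    kept_indices: list[int]
    dropped_ids: list[str]
    threshold: float
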
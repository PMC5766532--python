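"""Missing-variable filtering: the 80% rule and its group-wise variant.

The plain rule drops a metabolite whose overall non-missing fraction falls
below a threshold (default 80%). The modified, group-wise rule drops a
metabolite only when its non-missing fraction is below the threshold in
EVERY biological group — a metabolite measured reliably in one phenotype is
kept, since it may be a differential metabolite that is simply absent in
the other group.
"""

from __future__ import annotations

import numpy as np

from ._types import AbundanceMatrix, FilterResult, GroupLabels

__all__ = ["filter_missing_variables"]


def filter_missing_variables(
    data: AbundanceMatrix,
    groups: GroupLabels | None = None,
    threshold: float = 0.8,
    groupwise: bool = True,
) -> FilterResult:
    """Drop unreliable missing variables before imputation.

    A column is kept when its non-missing fraction is >= ``threshold``
    overall (``groupwise=False``) or in at least one group
    (``groupwise=True``, requires ``groups``). The boundary is inclusive:
    exactly the threshold fraction observed is kept.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if groupwise and groups is None:
        raise ValueError("groupwise filtering requires group labels")

    observed = ~data.missing_mask
    if groupwise:
        assert groups is not None
        if len(groups) != data.n_samples:
            raise ValueError("group labels do not match the matrix rows")
        fractions = np.vstack([
            observed[idx].mean(axis=0)
            for idx in groups.group_indices().values()
        ])
        keep = (fractions >= threshold).any(axis=0)
    else:
        keep = observed.mean(axis=0) >= threshold

    kept_indices = [int(j) for j in np.flatnonzero(keep)]
    dropped_ids = [
        data.metabolite_ids[j] for j in np.flatnonzero(~keep)
    ]
    filtered = AbundanceMatrix(
        data.values[:, keep],
        list(data.sample_ids),
        [data.metabolite_ids[j] for j in kept_indices],
    )
    return FilterResult(
        filtered=filtered,
        kept_indices=kept_indices,
        dropped_ids=dropped_ids,
        threshold=float(threshold),
    )
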
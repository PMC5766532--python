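"""MCAR and left-censored MNAR missingness generators.

MCAR removes a fixed number of entries uniformly at random across the whole
matrix. MNAR emulates limit-of-quantification censoring: a random subset of
metabolites is designated as "missing variables", and for each one every
value strictly below a per-variable random quantile cutoff (uniform on
[0.30, 0.60] by default) is removed — the low tail is censored, exactly as
when a compound falls below its LOQ.
"""

from __future__ import annotations

import numpy as np

from ._types import AbundanceMatrix, MissingDataset

__all__ = [
    "generate_mcar",
    "generate_mnar",
    "proportion_grid",
]


def _require_complete(matrix: AbundanceMatrix) -> None:
    if matrix.n_missing:
        raise ValueError("input matrix must be complete (no missing entries)")


def _masked_copy(matrix: AbundanceMatrix, mask: np.ndarray) -> AbundanceMatrix:
    observed = matrix.values.copy()
    observed[mask] = np.nan
    return matrix.with_values(observed)


def generate_mcar(
    complete: AbundanceMatrix, proportion: float, seed: int
) -> MissingDataset:
    """Mask exactly ``round(proportion * n * p)`` entries uniformly.

    Rounding is round-half-even. Positions are drawn without replacement,
    so every entry has the same marginal inclusion probability.
    """
    _require_complete(complete)
    if not 0 <= proportion < 1:
        raise ValueError("proportion must lie in [0, 1)")
    n, p = complete.shape
    total = n * p
    n_mask = int(np.round(proportion * total))
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_mask, replace=False)
    mask = np.zeros(total, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(n, p)
    return MissingDataset(
        complete=complete.copy(),
        mask=mask,
        observed=_masked_copy(complete, mask),
        meta={
            "generator": "mcar",
            "proportion": float(proportion),
            "seed": int(seed),
            "n_masked": int(n_mask),
        },
    )


def generate_mnar(
    complete: AbundanceMatrix,
    var_proportion: float,
    cutoff_low: float = 0.30,
    cutoff_high: float = 0.60,
    seed: int = 0,
) -> MissingDataset:
    """Left-censor a random subset of metabolites below random quantiles.

    ``round(var_proportion * p)`` metabolites are picked uniformly; each
    gets an independent cutoff ``q ~ Uniform(cutoff_low, cutoff_high)`` and
    every entry strictly below the variable's empirical q-quantile
    (linear-interpolation convention) is masked. Cutoffs are recorded in
    ``meta["cutoffs"]``.
    """
    _require_complete(complete)
    if not 0 <= var_proportion <= 1:
        raise ValueError("var_proportion must lie in [0, 1]")
    if not 0 <= cutoff_low <= cutoff_high <= 1:
        raise ValueError("need 0 <= cutoff_low <= cutoff_high <= 1")
    n, p = complete.shape
    n_vars = int(np.round(var_proportion * p))
    rng = np.random.default_rng(seed)
    missing_vars = np.sort(rng.choice(p, size=n_vars, replace=False))

    mask = np.zeros((n, p), dtype=bool)
    cutoffs: dict[str, float] = {}
    for j in missing_vars:
        q = float(rng.uniform(cutoff_low, cutoff_high))
        col = complete.values[:, j]
        threshold = float(np.quantile(col, q))
        col_mask = col < threshold
        if col_mask.all():
            raise ValueError(
                f"variable {complete.metabolite_ids[j]!r} would lose all "
                "entries at its cutoff"
            )
        mask[:, j] = col_mask
        cutoffs[complete.metabolite_ids[j]] = q

    return MissingDataset(
        complete=complete.copy(),
        mask=mask,
        observed=_masked_copy(complete, mask),
        meta={
            "generator": "mnar",
            "var_proportion": float(var_proportion),
            "cutoff_range": (float(cutoff_low), float(cutoff_high)),
            "seed": int(seed),
            "missing_variables": [
                complete.metabolite_ids[j] for j in missing_vars
            ],
            "cutoffs": cutoffs,
        },
    )


def proportion_grid(kind: str) -> list[float]:
    """The benchmark grids: MCAR 2.5%..50% by 2.5%; MNAR 4%..80% by 4%."""
    if kind == "mcar":
        return [round(0.025 * i, 4) for i in range(1, 21)]
    if kind == "mnar":
        return [round(0.04 * i, 4) for i in range(1, 21)]
    raise ValueError(f"unknown kind {kind!r}; expected 'mcar' or 'mnar'")
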
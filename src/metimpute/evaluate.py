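"""Imputation scoring: NRMSE, sum of ranks, Procrustes errors, log-p correlation.

NRMSE is computed over the masked entries only,

    NRMSE = sqrt( mean((x_true - x_imp)^2) / var(x_true) ),

with both matrices z-scored by the complete matrix's column statistics so
that high-abundance metabolites do not dominate. The sum of ranks (SOR)
ranks methods per missing variable by NRMSE and sums the ranks — a
non-parametric comparison robust to the skewed errors left-censored
missingness produces. Procrustes errors compare PCA (unsupervised) or
PLS-DA (supervised) sample-score configurations of imputed versus complete
data after optimal translation, rotation/reflection and scaling. The log-p
correlation measures how well per-metabolite two-sample t-test results
survive imputation.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _procrustes
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from ._types import AbundanceMatrix, GroupLabels

__all__ = [
    "nrmse",
    "nrmse_per_variable",
    "sor",
    "pca_procrustes",
    "pls_procrustes",
    "logp_correlation",
]


def _check_pair(
    complete: AbundanceMatrix, imputed: AbundanceMatrix, mask: np.ndarray
) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if complete.shape != imputed.shape or mask.shape != complete.shape:
        raise ValueError("complete, imputed and mask must share one shape")
    if complete.n_missing or imputed.n_missing:
        raise ValueError("both matrices must be complete")
    return mask


def _zscore_pair(
    complete: AbundanceMatrix, imputed: AbundanceMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize both matrices with the COMPLETE matrix's column stats."""
    mu = complete.values.mean(axis=0)
    sd = complete.values.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (complete.values - mu) / sd, (imputed.values - mu) / sd


def nrmse(
    complete: AbundanceMatrix,
    imputed: AbundanceMatrix,
    mask: np.ndarray,
    zscore: bool = True,
) -> float:
    """Normalized root mean squared error over the masked entries.

    The denominator is the sample (n-1) variance of the true masked
    values. 0 is perfect; values near 1 mean the imputation is no more
    informative than the mean of the missing entries.
    """
    mask = _check_pair(complete, imputed, mask)
    if mask.sum() < 2:
        raise ValueError("need at least 2 masked entries")
    if zscore:
        truth, imp = _zscore_pair(complete, imputed)
    else:
        truth, imp = complete.values, imputed.values
    t = truth[mask]
    x = imp[mask]
    denom = t.var(ddof=1)
    if denom == 0:
        raise ValueError("masked true entries have zero variance")
    return float(np.sqrt(np.mean((t - x) ** 2) / denom))


def nrmse_per_variable(
    complete: AbundanceMatrix,
    imputed: AbundanceMatrix,
    mask: np.ndarray,
    zscore: bool = True,
) -> pd.Series:
    """Column-wise NRMSE over each missing variable's masked entries.

    Returns a Series indexed by metabolite ID covering the columns with at
    least one masked entry. Columns with fewer than 2 masked entries or
    zero variance of the masked truth are NaN (undefined) and are excluded
    from SOR with a warning.
    """
    mask = _check_pair(complete, imputed, mask)
    if zscore:
        truth, imp = _zscore_pair(complete, imputed)
    else:
        truth, imp = complete.values, imputed.values
    out: dict[str, float] = {}
    undefined: list[str] = []
    for j in np.flatnonzero(mask.any(axis=0)):
        mid = complete.metabolite_ids[j]
        t = truth[mask[:, j], j]
        x = imp[mask[:, j], j]
        if t.size < 2 or t.var(ddof=1) == 0:
            out[mid] = np.nan
            undefined.append(mid)
            continue
        out[mid] = float(np.sqrt(np.mean((t - x) ** 2) / t.var(ddof=1)))
    if undefined:
        warnings.warn(
            f"NRMSE undefined for variables {undefined} "
            "(fewer than 2 masked entries or zero variance)",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.Series(out, dtype=float)


def sor(per_variable_nrmse: Mapping[str, pd.Series]) -> dict[str, float]:
    """NRMSE-based sum of ranks across methods.

    For each missing variable, methods are ranked ascending by NRMSE
    (rank 1 = most accurate, ties averaged); each method's SOR is the sum
    of its ranks over all missing variables. With J methods and M
    variables the SORs always total M * J * (J + 1) / 2.
    """
    if not per_variable_nrmse:
        raise ValueError("need at least one method")
    methods = list(per_variable_nrmse)
    table = pd.DataFrame({m: per_variable_nrmse[m] for m in methods})
    index_sets = {frozenset(per_variable_nrmse[m].index) for m in methods}
    if len(index_sets) != 1:
        raise ValueError("methods were scored on different variable sets")
    defined = table.dropna(axis=0)
    if len(defined) < len(table):
        dropped = sorted(set(table.index) - set(defined.index))
        warnings.warn(
            f"variables excluded from SOR (undefined NRMSE): {dropped}",
            RuntimeWarning,
            stacklevel=2,
        )
    ranks = defined.rank(axis=1, method="average", ascending=True)
    return {m: float(ranks[m].sum()) for m in methods}


def _standardize_own(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - values.mean(axis=0)) / sd


def _procrustes_error(scores_a: np.ndarray, scores_b: np.ndarray) -> float:
    """Scaled Procrustes residual between two score configurations.

    Both configurations are centred and normalized to unit sum of squares,
    then the second is optimally rotated/reflected and scaled onto the
    first; the residual sum of squares lies in [0, 1] and is 0 exactly
    when the configurations are similarity-equivalent.
    """
    _, _, disparity = _procrustes(scores_a, scores_b)
    return float(disparity)


def pca_procrustes(
    complete: AbundanceMatrix,
    imputed: AbundanceMatrix,
    n_pcs: int = 2,
) -> float:
    """Procrustes error between PCA sample scores of imputed vs complete.

    Each matrix is column-standardized with its own statistics before PCA;
    the first ``n_pcs`` components (the bulk of the variance) are compared.
    """
    if complete.shape != imputed.shape:
        raise ValueError("matrices must share one shape")
    if complete.n_missing or imputed.n_missing:
        raise ValueError("both matrices must be complete")
    if n_pcs > min(complete.shape):
        raise ValueError("n_pcs exceeds the matrix dimensions")
    scores = []
    for m in (complete, imputed):
        pca = PCA(n_components=n_pcs, svd_solver="full")
        scores.append(pca.fit_transform(_standardize_own(m.values)))
    return _procrustes_error(scores[0], scores[1])


def pls_procrustes(
    complete: AbundanceMatrix,
    imputed: AbundanceMatrix,
    groups: GroupLabels,
    n_comp: int = 2,
) -> float:
    """Procrustes error between PLS-DA sample scores of imputed vs complete.

    PLS-DA regresses a 0/1 group indicator on the column-standardized
    matrix (NIPALS); the first ``n_comp`` X-score components of each matrix
    are superimposed as in :func:`pca_procrustes`.
    """
    if len(groups) != complete.n_samples:
        raise ValueError("group labels do not match the matrix rows")
    if complete.n_missing or imputed.n_missing:
        raise ValueError("both matrices must be complete")
    y = groups.indicator()
    scores = []
    for m in (complete, imputed):
        pls = PLSRegression(n_components=n_comp, scale=True)
        pls.fit(_standardize_own(m.values), y)
        scores.append(np.asarray(pls.x_scores_))
    return _procrustes_error(scores[0], scores[1])


def logp_correlation(
    complete: AbundanceMatrix,
    imputed: AbundanceMatrix,
    groups: GroupLabels,
    restrict_to: Sequence[str] | None = None,
    welch: bool = False,
) -> float:
    """Pearson r between log t-test p-values on complete vs imputed data.

    A two-sample Student's t-test (pooled variance; ``welch=True`` for
    unequal variances) is run per metabolite in scope; the natural-log
    p-values of the two matrices are then correlated. Columns whose test is
    undefined (constant within both groups) are dropped with a warning.
    ``restrict_to`` limits the scope, e.g. to the missing variables when
    evaluating left-censored missingness.
    """
    if len(groups) != complete.n_samples:
        raise ValueError("group labels do not match the matrix rows")
    if complete.n_missing or imputed.n_missing:
        raise ValueError("both matrices must be complete")
    groups.require_min_group_size(3)
    if restrict_to is None:
        cols = list(range(complete.n_metabolites))
    else:
        index = {m: j for j, m in enumerate(complete.metabolite_ids)}
        unknown = [m for m in restrict_to if m not in index]
        if unknown:
            raise ValueError(f"unknown metabolite IDs: {unknown}")
        cols = [index[m] for m in restrict_to]
    if len(cols) < 3:
        raise ValueError("need at least 3 metabolites in scope")

    idx = groups.group_indices()
    (ia, ib) = (idx[c] for c in groups.classes)
    logp = {"complete": [], "imputed": []}
    dropped: list[str] = []
    for j in cols:
        ps = []
        for key, m in (("complete", complete), ("imputed", imputed)):
            res = stats.ttest_ind(
                m.values[ia, j], m.values[ib, j], equal_var=not welch
            )
            ps.append(res.pvalue)
        if not all(np.isfinite(ps)) or any(p <= 0 for p in ps):
            dropped.append(complete.metabolite_ids[j])
            continue
        logp["complete"].append(np.log(ps[0]))
        logp["imputed"].append(np.log(ps[1]))
    if dropped:
        warnings.warn(
            f"columns dropped from log-p correlation: {dropped}",
            RuntimeWarning,
            stacklevel=2,
        )
    if len(logp["complete"]) < 3:
        raise ValueError("fewer than 3 usable metabolites for correlation")
    r, _ = stats.pearsonr(logp["complete"], logp["imputed"])
    return float(r)
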
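"""Eight imputation methods for metabolomics abundance matrices.

Determined-value methods (zero, half-minimum, mean, median) replace each
missing entry with a per-column constant. kNN, iterative SVD and iterative
random-forest imputation exploit between-sample / between-metabolite
correlation and suit values missing (completely) at random. QRILC draws
from a truncated normal fitted to the observed upper tail of each
metabolite and suits left-censored, below-LOQ missingness.

Every method preserves observed entries bit-identically and returns a
complete matrix wrapped in a :class:`~metimpute._types.MethodResult`.
"""

from __future__ import annotations

import warnings
from typing import Any

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from ._types import AbundanceMatrix, MethodResult

__all__ = [
    "METHODS",
    "impute",
    "impute_constant",
    "impute_knn",
    "impute_svd",
    "impute_rf",
    "impute_qrilc",
]

CONSTANT_STRATEGIES = ("zero", "hm", "mean", "median")
METHODS = ("zero", "hm", "mean", "median", "knn", "svd", "rf", "qrilc")


def _finish(
    data: AbundanceMatrix,
    filled: np.ndarray,
    method: str,
    params: dict[str, Any],
    seed: int | None = None,
) -> MethodResult:
    """Restore observed entries exactly and wrap the result."""
    miss = data.missing_mask
    out = np.where(miss, filled, data.values)
    return MethodResult(
        imputed=data.with_values(out), method=method, params=params, seed=seed
    )


def impute_constant(data: AbundanceMatrix, strategy: str) -> MethodResult:
    """Per-column constant replacement: 0, half-minimum, mean or median.

    Half-minimum (HM) uses half the minimum observed value of the column —
    the conventional stand-in for a below-LOQ measurement.
    """
    if strategy not in CONSTANT_STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of "
            f"{CONSTANT_STRATEGIES}"
        )
    values = data.values
    miss = data.missing_mask
    filled = values.copy()
    if strategy == "zero":
        filled[miss] = 0.0
        return _finish(data, filled, "zero", {})

    for j in np.flatnonzero(miss.any(axis=0)):
        obs = values[~miss[:, j], j]
        if obs.size == 0:
            raise ValueError(
                f"column {data.metabolite_ids[j]!r} has no observed entries; "
                f"{strategy} imputation is undefined"
            )
        if strategy == "hm":
            fill = obs.min() / 2.0
        elif strategy == "mean":
            fill = obs.mean()
        else:
            fill = float(np.median(obs))
        filled[miss[:, j], j] = fill
    return _finish(data, filled, strategy, {})


def impute_knn(data: AbundanceMatrix, k: int = 10) -> MethodResult:
    """Sample-wise k-nearest-neighbour imputation.

    Distances between samples use the Euclidean metric over the variables
    observed in both samples, scaled by the number of shared variables so
    samples with different missingness patterns are comparable. Each
    missing entry becomes the unweighted mean of the k nearest samples that
    observe that variable; the column mean is the fallback when no eligible
    neighbour exists.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = data.values
    miss = data.missing_mask
    n, p = values.shape
    if n < 2:
        raise ValueError("kNN imputation needs at least 2 samples")
    filled = values.copy()
    col_means = np.array([
        values[~miss[:, j], j].mean() if (~miss[:, j]).any() else np.nan
        for j in range(p)
    ])

    obs = ~miss
    for i in np.flatnonzero(miss.any(axis=1)):
        shared = obs[i] & obs  # (n, p) shared-observation indicator
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, values[i] - values, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff**2).sum(axis=1) / n_shared)
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        order = np.argsort(dist, kind="stable")
        for j in np.flatnonzero(miss[i]):
            donors = [
                t for t in order if obs[t, j] and np.isfinite(dist[t])
            ][:k]
            if donors:
                filled[i, j] = values[donors, j].mean()
            elif np.isfinite(col_means[j]):
                filled[i, j] = col_means[j]
            else:
                raise ValueError(
                    f"column {data.metabolite_ids[j]!r} has no observed "
                    "entries; kNN has no fallback"
                )
    return _finish(data, filled, "knn", {"k": int(k)})


def impute_svd(
    data: AbundanceMatrix,
    k: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MethodResult:
    """Iterative rank-k SVD imputation on the standardized matrix.

    Missing entries start at the column means (0 on the standardized
    scale). Each sweep standardizes the completed matrix with its current
    column means/SDs, reconstructs it from the top-k singular vectors,
    inverts the standardization and overwrites only the missing positions,
    until the relative change of the imputed values drops below ``tol``.
    Re-estimating the column statistics each sweep (rather than freezing
    the observed-entry statistics) removes the bias the missing entries
    induce in the centring, so an exactly low-rank matrix is recovered
    exactly. Observed entries are never altered.
    """
    n, p = data.shape
    if not 1 <= k <= min(n, p):
        raise ValueError("k must be in [1, min(n_samples, n_metabolites)]")
    values = data.values
    miss = data.missing_mask
    if not miss.any():
        return _finish(data, values.copy(), "svd", {"k": int(k)})
    if (np.sum(~miss, axis=0) < 2).any():
        bad = np.flatnonzero(np.sum(~miss, axis=0) < 2)
        raise ValueError(
            "columns with fewer than 2 observed entries: "
            f"{[data.metabolite_ids[j] for j in bad]}"
        )

    filled = values.copy()
    for j in range(p):
        filled[miss[:, j], j] = values[~miss[:, j], j].mean()

    converged = False
    for _ in range(max_iter):
        means = filled.mean(axis=0)
        sds = filled.std(axis=0, ddof=1)
        sds[sds == 0] = 1.0
        z = (filled - means) / sds
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        recon = (u[:, :k] * s[:k]) @ vt[:k] * sds + means
        new_missing = recon[miss]
        old_missing = filled[miss]
        denom = max(float(np.sum(new_missing**2)), np.finfo(float).tiny)
        change = float(np.sum((new_missing - old_missing) ** 2)) / denom
        filled[miss] = new_missing
        if change < tol:
            converged = True
            break
    params: dict[str, Any] = {"k": int(k), "tol": tol, "converged": converged}
    if not converged:
        warnings.warn(
            f"SVD imputation did not converge within {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return _finish(data, filled, "svd", params)


def impute_rf(
    data: AbundanceMatrix,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
) -> MethodResult:
    """Iterative random-forest imputation (missForest scheme).

    Missing entries start at the column means. Columns are visited in order
    of ascending missing count; each gets a random-forest regression of its
    observed entries on all other columns, which then predicts its missing
    entries. Sweeps repeat until the sum of squared changes between
    successive sweeps first increases, at which point the previous sweep's
    matrix is returned.
    """
    values = data.values
    miss = data.missing_mask
    n, p = values.shape
    if p < 2:
        raise ValueError("random-forest imputation needs at least 2 columns")
    if not miss.any():
        return _finish(
            data, values.copy(), "rf", {"n_trees": int(n_trees)}, seed
        )
    if (~miss).sum(axis=0).min() == 0:
        bad = np.flatnonzero((~miss).sum(axis=0) == 0)
        raise ValueError(
            "columns with no observed entries: "
            f"{[data.metabolite_ids[j] for j in bad]}"
        )

    rng = np.random.default_rng(seed)
    filled = values.copy()
    col_means = np.array([values[~miss[:, j], j].mean() for j in range(p)])
    for j in range(p):
        filled[miss[:, j], j] = col_means[j]

    missing_cols = np.flatnonzero(miss.any(axis=0))
    order = missing_cols[np.argsort(miss[:, missing_cols].sum(axis=0),
                                    kind="stable")]
    prev = filled.copy()
    prev_diff = np.inf
    n_sweeps = 0
    for _ in range(max_iter):
        for j in order:
            obs_rows = ~miss[:, j]
            others = np.delete(np.arange(p), j)
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            forest.fit(filled[np.ix_(obs_rows, others)], values[obs_rows, j])
            filled[miss[:, j], j] = forest.predict(
                filled[np.ix_(~obs_rows, others)]
            )
        n_sweeps += 1
        diff = float(np.sum((filled[miss] - prev[miss]) ** 2))
        if diff >= prev_diff:
            filled = prev  # last sweep made things worse; keep the previous
            break
        prev = filled.copy()
        prev_diff = diff
    return _finish(
        data,
        filled,
        "rf",
        {"n_trees": int(n_trees), "max_iter": int(max_iter),
         "n_sweeps": n_sweeps},
        seed,
    )


def _qrilc_fit(log_obs: np.ndarray, n_total: int) -> tuple[float, float]:
    """Estimate (mu, sigma) of the uncensored log-normal by tail regression.

    The sorted observed log-values occupy overall ranks m+1..n of the full
    variable; regressing them on the standard-normal quantiles of their
    Blom plotting positions (i - 0.375)/(n + 0.25) recovers the mean and SD
    of the underlying normal despite the censored low tail.
    """
    m = n_total - log_obs.size
    ranks = np.arange(m + 1, n_total + 1)
    pp = (ranks - 0.375) / (n_total + 0.25)
    z = stats.norm.ppf(pp)
    design = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(design, np.sort(log_obs), rcond=None)
    return float(coef[0]), float(coef[1])


def impute_qrilc(
    data: AbundanceMatrix,
    seed: int = 0,
    min_observed: int = 5,
) -> MethodResult:
    """Quantile regression imputation of left-censored data.

    Per missing variable: log-transform the observed entries, estimate the
    mean and SD of the uncensored normal from the observed upper tail
    (see :func:`_qrilc_fit`), then draw each missing entry from that normal
    truncated above at the estimated censoring point
    ``mu + sigma * Phi^-1(missing fraction)`` and exponentiate back.
    Variables with fewer than ``min_observed`` observed entries, or a
    non-positive fitted SD, fall back to half-minimum with a warning.
    """
    values = data.values
    miss = data.missing_mask
    n, p = values.shape
    with np.errstate(invalid="ignore"):
        if np.any(values[~miss] <= 0):
            raise ValueError(
                "QRILC requires strictly positive observed values "
                "(log-transform)"
            )
    rng = np.random.default_rng(seed)
    filled = values.copy()
    fallbacks: list[str] = []
    for j in np.flatnonzero(miss.any(axis=0)):
        col_miss = miss[:, j]
        obs = values[~col_miss, j]
        m = int(col_miss.sum())
        mu = sigma = np.nan
        if obs.size >= min_observed:
            mu, sigma = _qrilc_fit(np.log(obs), n)
        if not np.isfinite(sigma) or sigma <= 0:
            fallbacks.append(data.metabolite_ids[j])
            filled[col_miss, j] = obs.min() / 2.0
            continue
        censor = mu + sigma * stats.norm.ppf(m / n)
        draws = stats.truncnorm.rvs(
            a=-np.inf,
            b=(censor - mu) / sigma,
            loc=mu,
            scale=sigma,
            size=m,
            random_state=rng,
        )
        filled[col_miss, j] = np.exp(draws)
    if fallbacks:
        warnings.warn(
            "QRILC fell back to half-minimum for variables with too few "
            f"observed entries or degenerate fits: {fallbacks}",
            RuntimeWarning,
            stacklevel=2,
        )
    return _finish(
        data, filled, "qrilc",
        {"min_observed": int(min_observed), "fallback_hm": fallbacks}, seed,
    )


def impute(
    data: AbundanceMatrix,
    method: str,
    seed: int | None = None,
    **params: Any,
) -> MethodResult:
    """Dispatch to any of the eight methods by name."""
    if method in CONSTANT_STRATEGIES:
        return impute_constant(data, method)
    if method == "knn":
        return impute_knn(data, **params)
    if method == "svd":
        return impute_svd(data, **params)
    if method == "rf":
        return impute_rf(data, seed=0 if seed is None else seed, **params)
    if method == "qrilc":
        return impute_qrilc(data, seed=0 if seed is None else seed, **params)
    raise ValueError(f"unknown imputation method {method!r}; "
                     f"expected one of {METHODS}")
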
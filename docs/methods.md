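# Methods

## Synthetic data model

`metimpute.synth` draws complete abundance matrices from an exponentiated
factor model on the natural-log scale:

    log X = S L + d g + E,      X in R^(n×p), S in R^(n×r), L in R^(r×p)

- The first column of `S` is ~N(1, 0.2) and the first row of `L` holds
  per-metabolite baseline offsets drawn uniformly from [1, 5] (log units):
  metabolites span roughly e^1–e^5 in typical abundance, with mild
  dilution-like per-sample baseline variation. The remaining factor scores
  and loadings are standard normal, inducing the strong between-metabolite
  correlation imputation methods rely on.
- `g` is a 0/1 indicator of the second of two balanced phenotype groups
  and `d` adds a log-scale mean shift `effect_size` to the first
  `n_affected` metabolites (default 0 — unlabeled data).
- `E` is i.i.d. N(0, noise_sd²); default `noise_sd = 0.1` log units, small
  relative to the factor variance, matching the tight technical replication
  of targeted assays.

Consequences used by the tests: all values are strictly positive and
right-skewed; with `noise_sd = 0` the log-matrix has rank exactly
`latent_rank` (the offsets ride on the first factor); the default rank is
5, the same number of components the SVD imputer assumes. The generator
does **not** emulate instrument drift, batch effects, heteroscedastic
(abundance-dependent) noise, or QC samples — conclusions drawn from it
speak to the relative behaviour of the methods under the stated model, not
to any particular instrument's data.

## Missingness generators

- **MCAR** masks exactly `round(proportion · n · p)` entries drawn
  uniformly without replacement (round-half-even; the exact count makes
  tests deterministic). Every entry has equal inclusion probability.
- **MNAR** designates `round(var_proportion · p)` metabolites as missing
  variables; each receives an independent cutoff `q ~ Uniform(0.30,
  0.60)` and every value *strictly below* the variable's empirical
  q-quantile (linear-interpolation convention) is masked. Left-censoring
  is exact by construction: the largest masked value is below the smallest
  surviving value of that variable. Cutoffs ≤ 0.60 mean a variable can
  never lose all entries, but the generator still errors if that occurs
  (e.g. with user-supplied cutoff ranges near 1).

The benchmark grids are 2.5%–50% in steps of 2.5% (MCAR, fraction of all
entries) and 4%–80% in steps of 4% (MNAR, fraction of metabolites).

## Filtering

The plain 80% rule keeps a metabolite whose overall non-missing fraction
is ≥ the threshold; the group-wise (modified) rule keeps it when that
holds in **at least one** group, dropping it only when unreliable in every
group — this protects potential differential metabolites that are absent
in one phenotype. The boundary is inclusive (exactly 80% observed is
kept), and the threshold is exposed on a 0–1 scale.

## Imputation methods

All methods preserve observed entries bit-identically and return complete
matrices.

- **zero / hm / mean / median** — per-column constants (0, half the
  observed minimum, observed mean, observed median).
- **kNN** (`k = 10`) — sample-wise: distances between samples are
  Euclidean over the variables observed in both, divided by the number of
  shared variables so differently-masked samples are comparable; each
  missing entry is the unweighted mean of the k nearest samples observing
  that variable, with the column mean as fallback. With highly skewed raw
  abundances, distances are dominated by high-abundance metabolites;
  log-transforming before imputation is advisable (see below).
- **SVD** (`k = 5`, `tol = 1e-6`) — iterative low-rank completion:
  missing entries start at the column means; each sweep standardizes the
  completed matrix by its current column means/SDs, reconstructs from the
  top k singular vectors, and overwrites the missing positions until the
  relative change falls below `tol`. Re-estimating the column statistics
  every sweep (rather than freezing the observed-entry statistics) removes
  the centring bias missing entries induce; this is what makes an exactly
  rank-k matrix recoverable to machine precision, a property the tests
  exercise. Non-convergence within `max_iter` is reported in the result's
  params, not raised.
- **RF** (`n_trees = 100`, missForest scheme) — missing entries start at
  column means; columns are visited in ascending missing count; each gets
  a random-forest regression (mtry = √p) of its observed entries on all
  other columns; sweeps repeat until the sum of squared changes first
  increases, returning the previous sweep. Deterministic given the seed.
- **QRILC** — per metabolite with missing entries: the sorted observed
  log-values occupy overall ranks m+1…n; regressing them on
  standard-normal quantiles of the Blom plotting positions
  (i − 0.375)/(n + 0.25) estimates the mean and SD of the uncensored
  normal; each missing value is then drawn from that normal truncated
  above at μ̂ + σ̂·Φ⁻¹(m/n) and exponentiated, guaranteeing positive
  values below the estimated LOQ. Variables with fewer than 5 observed
  entries or a non-positive fitted slope fall back to half-minimum with a
  warning. The fit is per metabolite because censoring (an LOQ) is a
  property of a compound, not of a sample.

### Scale conventions

Imputation operates on the matrix as given. The exact-recovery tests and
the SVD/kNN guidance assume log-transformed input when the data are
log-normal, because the low-rank/correlation structure lives on the log
scale; QRILC log-transforms internally. The benchmark intentionally runs
all methods on the raw scale — the setting a naive user faces.

## Evaluation

- **NRMSE** (masked entries only): both matrices are z-scored with the
  *complete* matrix's column means and SDs (sample, n−1), so the metric
  isolates imputation error and high-abundance metabolites do not
  dominate; the denominator is the sample variance of the masked true
  values. Under MCAR, mean imputation's numerator approaches that
  denominator, so its NRMSE plateaus at ≈1 — a useful calibration point.
- **SOR**: per missing variable, methods are ranked ascending by NRMSE
  (ties averaged) and ranks are summed; totals are conserved at
  M·J·(J+1)/2. Variables whose per-column NRMSE is undefined (fewer than
  2 masked entries, zero variance) are excluded with a warning.
- **PCA/PLS-Procrustes**: sample scores (top 2 PCs of the
  column-standardized matrix, or the first 2 PLS-DA X-scores against a
  0/1 group indicator) of imputed and complete data are superimposed
  allowing translation, rotation/reflection and isotropic scaling after
  normalizing both configurations to unit centred sum of squares; the
  residual sum of squares lies in [0, 1] and is 0 iff the configurations
  are similarity-equivalent. PCA sign/rotation ambiguity is therefore
  irrelevant (a tested property).
- **log-p correlation**: per-metabolite two-sample Student's t-tests
  (pooled variance; a Welch option exists) on complete and imputed data;
  Pearson r between the natural-log p-values (the r is log-base
  invariant). For MNAR the scope is restricted to the missing variables;
  for MCAR all variables are used.

## Benchmark pipeline

Every method within one (proportion, repeat) cell is scored against the
identical mask, so comparisons are paired. Repeats (default 3, seeds
`base_seed + repeat`) are an engineering addition — single curves are
noisy for the stochastic methods — and the reported value is the mean.
The scaled-down reproduction used by the tests and `scripts/acceptance.py`
runs n = 100 samples × p = 50 metabolites at three proportions per regime
with three repeats; this size keeps the full sweep to a few minutes while
leaving the method ranking stable across seeds.

## Known limitations

- The MNAR generator censors sharply at a quantile; real LOQ censoring is
  soft (detection probability rises smoothly with abundance), which
  slightly favours QRILC's hard-truncation model here.
- QRILC's tail regression assumes log-normal metabolite distributions;
  strongly non-normal log distributions bias (μ̂, σ̂).
- kNN and SVD results on raw-scale log-normal data are poor by design of
  the scale convention above; users should log-transform first.
- The group-wise filter assumes exactly two groups, as does PLS-DA and
  the t-test evaluation.
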
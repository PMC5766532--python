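import warnings

import numpy as np
import pandas as pd
import pytest

import metimpute as mi
from metimpute import evaluate as ev


def brute_force_nrmse(true_z, imp_z, mask):
    """Literal loop implementation of the masked-entry NRMSE."""
    diffs, truths = [], []
    n, p = true_z.shape
    for i in range(n):
        for j in range(p):
            if mask[i, j]:
                diffs.append((true_z[i, j] - imp_z[i, j]) ** 2)
                truths.append(true_z[i, j])
    truths = np.array(truths)
    return np.sqrt(np.mean(diffs) / truths.var(ddof=1))


def zscore_by(ref, values):
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    return (values - mu) / sd


def random_instance(rng, n=20, p=10):
    truth = rng.uniform(0.5, 10.0, size=(n, p))
    imputed = truth.copy()
    mask = rng.random((n, p)) < 0.2
    # ensure at least 2 masked entries and some per-column structure
    mask[0, 0] = mask[1, 0] = True
    imputed[mask] = rng.uniform(0.5, 10.0, size=mask.sum())
    ids = [f"s{i}" for i in range(n)], [f"m{j}" for j in range(p)]
    return (mi.AbundanceMatrix(truth, *ids),
            mi.AbundanceMatrix(imputed, *ids), mask)


class TestNrmse:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            complete, imputed, mask = random_instance(rng)
            expected = brute_force_nrmse(
                zscore_by(complete.values, complete.values),
                zscore_by(complete.values, imputed.values),
                mask,
            )
            assert ev.nrmse(complete, imputed, mask) == pytest.approx(
                expected, abs=1e-12
            )

    def test_hand_computed_value(self):
        # masked z-scored truths [-1, 0, 1] vs imputed [0, 0, 0]:
        # MSE = 2/3, sample variance = 1 -> sqrt(2/3) ~ 0.8165
        truth = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [2.0, 7.0]])
        imputed = truth.copy()
        imputed[:3, 0] = 2.0  # z-score of 2.0 in column 0 is 0
        mask = np.zeros_like(truth, dtype=bool)
        mask[:3, 0] = True
        ids = ["s1", "s2", "s3", "s4"], ["m1", "m2"]
        complete = mi.AbundanceMatrix(truth, *ids)
        # column 0 of truth: mean 2, sd ... z-scores of [1,2,3] = [-1,0,1]/sd
        value = ev.nrmse(complete, mi.AbundanceMatrix(imputed, *ids), mask)
        assert value == pytest.approx(np.sqrt(2 / 3), abs=1e-12)

    def test_perfect_imputation_is_zero(self, small_complete):
        matrix, _ = small_complete
        ds = mi.generate_mcar(matrix, 0.2, seed=1)
        assert ev.nrmse(ds.complete, ds.complete, ds.mask) == 0.0

    def test_zero_variance_masked_truth_errors(self):
        truth = np.full((4, 3), 5.0)
        truth[:, 1] = [1, 2, 3, 4]
        ids = ["a", "b", "c", "d"], ["m1", "m2", "m3"]
        mask = np.zeros_like(truth, dtype=bool)
        mask[:2, 0] = True  # masked truths both 5.0
        with pytest.raises(ValueError, match="variance"):
            ev.nrmse(mi.AbundanceMatrix(truth, *ids),
                     mi.AbundanceMatrix(truth * 1.01, *ids), mask)


class TestNrmsePerVariable:
    def test_matches_per_column_brute_force(self):
        rng = np.random.default_rng(7)
        complete, imputed, mask = random_instance(rng, n=30, p=6)
        tz = zscore_by(complete.values, complete.values)
        iz = zscore_by(complete.values, imputed.values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_var = ev.nrmse_per_variable(complete, imputed, mask)
        for mid, value in per_var.items():
            j = complete.metabolite_ids.index(mid)
            if mask[:, j].sum() < 2:
                continue
            expected = brute_force_nrmse(
                tz[:, [j]], iz[:, [j]], mask[:, [j]]
            )
            assert value == pytest.approx(expected, abs=1e-12)

    def test_single_missing_variable_consistency(self, small_complete):
        matrix, _ = small_complete
        mask = np.zeros(matrix.shape, dtype=bool)
        mask[:10, 3] = True
        imputed = matrix.values.copy()
        imputed[mask] *= 1.3
        imputed_m = matrix.with_values(imputed)
        per_var = ev.nrmse_per_variable(matrix, imputed_m, mask)
        assert len(per_var) == 1
        assert per_var.iloc[0] == pytest.approx(
            ev.nrmse(matrix, imputed_m, mask)
        )


class TestSor:
    def test_uniform_winner(self):
        a = pd.Series({"m1": 0.1, "m2": 0.1})
        b = pd.Series({"m1": 0.2, "m2": 0.2})
        assert ev.sor({"A": a, "B": b}) == {"A": 2.0, "B": 4.0}

    def test_split_ranks(self):
        a = pd.Series({"m1": 0.1, "m2": 0.2})
        b = pd.Series({"m1": 0.3, "m2": 0.15})
        assert ev.sor({"A": a, "B": b}) == {"A": 3.0, "B": 3.0}

    def test_ties_get_average_ranks(self):
        a = pd.Series({"m1": 0.1})
        b = pd.Series({"m1": 0.1})
        c = pd.Series({"m1": 0.5})
        result = ev.sor({"A": a, "B": b, "C": c})
        assert result == {"A": 1.5, "B": 1.5, "C": 3.0}

    def test_conservation_with_random_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_methods = int(rng.integers(2, 6))
            n_vars = int(rng.integers(1, 8))
            values = rng.integers(0, 3, size=(n_vars, n_methods)) / 10
            table = {
                f"meth{k}": pd.Series(values[:, k],
                                      index=[f"m{i}" for i in range(n_vars)])
                for k in range(n_methods)
            }
            total = sum(ev.sor(table).values())
            assert total == pytest.approx(
                n_vars * n_methods * (n_methods + 1) / 2
            )

    def test_mismatched_variable_sets_rejected(self):
        a = pd.Series({"m1": 0.1})
        b = pd.Series({"m2": 0.1})
        with pytest.raises(ValueError, match="different variable sets"):
            ev.sor({"A": a, "B": b})


class TestProcrustes:
    def test_identical_is_zero(self, small_complete):
        matrix, _ = small_complete
        assert ev.pca_procrustes(matrix, matrix) == pytest.approx(0, abs=1e-9)

    def test_similarity_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.standard_normal((30, 2))
        theta = np.pi / 2
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        transformed = 2.0 * scores @ rot + np.array([5.0, -3.0])
        from metimpute.evaluate import _procrustes_error
        assert _procrustes_error(scores, transformed) == pytest.approx(
            0, abs=1e-12
        )
        reflected = scores * np.array([-1.0, 1.0])
        assert _procrustes_error(scores, reflected) == pytest.approx(
            0, abs=1e-12
        )

    def test_error_increases_with_noise(self, small_complete):
        matrix, _ = small_complete
        rng = np.random.default_rng(5)
        noise = rng.standard_normal(matrix.shape)
        errors = []
        for sd in [0.01, 0.1, 0.5]:
            perturbed = matrix.with_values(
                np.abs(matrix.values + sd * matrix.values.std() * noise)
            )
            errors.append(ev.pca_procrustes(matrix, perturbed))
        assert errors[0] < errors[1] < errors[2]

    def test_bounded_unit_interval(self, small_complete):
        matrix, _ = small_complete
        ds = mi.generate_mcar(matrix, 0.3, seed=2)
        imputed = mi.impute(ds.observed, "zero").imputed
        err = ev.pca_procrustes(ds.complete, imputed)
        assert 0 <= err <= 1

    def test_pls_identical_is_zero(self, labeled_complete):
        matrix, groups = labeled_complete
        assert ev.pls_procrustes(matrix, matrix, groups) == pytest.approx(
            0, abs=1e-9
        )

    def test_pls_rf_beats_mean_on_mcar(self, labeled_complete):
        matrix, groups = labeled_complete
        ds = mi.generate_mcar(matrix, 0.10, seed=4)
        rf = mi.impute(ds.observed, "rf", seed=4).imputed
        mean = mi.impute(ds.observed, "mean").imputed
        assert (ev.pls_procrustes(ds.complete, rf, groups)
                < ev.pls_procrustes(ds.complete, mean, groups))


class TestLogpCorrelation:
    def test_perfect_imputation_r_one(self, labeled_complete):
        matrix, groups = labeled_complete
        assert ev.logp_correlation(matrix, matrix, groups) == pytest.approx(
            1.0
        )

    def test_log_base_invariance(self, labeled_complete):
        """Pearson r is invariant to the log base, so ln is as good as log10.

        Verified indirectly: correlating ln p with (ln p)/ln(10) by hand
        gives the same r the metric reports.
        """
        matrix, groups = labeled_complete
        ds = mi.generate_mcar(matrix, 0.2, seed=6)
        imputed = mi.impute(ds.observed, "knn").imputed
        from scipy import stats
        idx = groups.group_indices()
        ia, ib = idx.values()
        ln_c, ln_i = [], []
        for j in range(matrix.n_metabolites):
            pc = stats.ttest_ind(ds.complete.values[ia, j],
                                 ds.complete.values[ib, j]).pvalue
            pi = stats.ttest_ind(imputed.values[ia, j],
                                 imputed.values[ib, j]).pvalue
            ln_c.append(np.log(pc))
            ln_i.append(np.log(pi))
        r_ln = stats.pearsonr(ln_c, ln_i).statistic
        r_log10 = stats.pearsonr(
            np.array(ln_c) / np.log(10), np.array(ln_i) / np.log(10)
        ).statistic
        assert r_ln == pytest.approx(r_log10, abs=1e-12)
        assert ev.logp_correlation(ds.complete, imputed, groups) == (
            pytest.approx(r_ln, abs=1e-12)
        )

    def test_destroyed_signal_drives_r_down(self, labeled_complete):
        matrix, groups = labeled_complete
        rng = np.random.default_rng(8)
        shuffled = matrix.values.copy()
        for j in range(matrix.n_metabolites):
            rng.shuffle(shuffled[:, j])
        scrambled = matrix.with_values(shuffled)
        r = ev.logp_correlation(matrix, scrambled, groups)
        assert abs(r) < 0.5

    def test_restrict_to_subset(self, labeled_complete):
        matrix, groups = labeled_complete
        subset = matrix.metabolite_ids[:5]
        r = ev.logp_correlation(matrix, matrix, groups, restrict_to=subset)
        assert r == pytest.approx(1.0)
        with pytest.raises(ValueError, match="unknown"):
            ev.logp_correlation(matrix, matrix, groups,
                                restrict_to=["nope"])
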
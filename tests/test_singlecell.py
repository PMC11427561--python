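import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diame.singlecell import (
    cluster_correlation,
    covariation_matrix,
    differential_expression,
    impute_knn,
    impute_min,
    zscore_rows,
)


def grouped_matrix(control: np.ndarray, treated: np.ndarray, proteins=None):
    n_c, n_t = control.shape[1], treated.shape[1]
    cols = [f"c{i}" for i in range(n_c)] + [f"t{i}" for i in range(n_t)]
    mat = pd.DataFrame(np.hstack([control, treated]), columns=cols, index=proteins)
    groups = pd.Series(["control"] * n_c + ["treated"] * n_t, index=cols)
    return mat, groups


class TestDifferentialExpression:
    def test_identical_groups_zero_fc_unit_p(self):
        vals = np.array([[1.0, 2.0, 3.0]])
        mat, groups = grouped_matrix(vals, vals.copy())
        res = differential_expression(mat, groups, "control", "treated")
        assert res["log2_fc"].iloc[0] == 0.0
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_pooled_t_matches_closed_form(self):
        control = np.array([[0.0, 0.01, -0.01]])
        treated = np.array([[1.0, 1.01, 0.99]])
        mat, groups = grouped_matrix(control, treated)
        res = differential_expression(mat, groups, "control", "treated")
        # pooled two-sample t computed from first principles
        a, b = treated[0], control[0]
        sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p = 2 * stats.t.sf(abs(t), df=4)
        assert res["log2_fc"].iloc[0] == pytest.approx(1.0)
        assert res["p_value"].iloc[0] == pytest.approx(p, rel=1e-9)

    def test_welch_option_differs_under_unequal_variance(self):
        rng = np.random.default_rng(0)
        control = rng.normal(0, 0.1, size=(1, 8))
        treated = rng.normal(1, 2.0, size=(1, 8))
        mat, groups = grouped_matrix(control, treated)
        pooled = differential_expression(mat, groups, "control", "treated")
        welch = differential_expression(mat, groups, "control", "treated", welch=True)
        assert pooled["p_value"].iloc[0] != welch["p_value"].iloc[0]

    def test_underobserved_protein_skipped(self):
        control = np.array([[1.0, 2.0, 3.0], [1.0, np.nan, np.nan]])
        treated = np.array([[2.0, 3.0, 4.0], [2.0, 3.0, 4.0]])
        mat, groups = grouped_matrix(control, treated, proteins=["ok", "thin"])
        res = differential_expression(mat, groups, "control", "treated")
        assert list(res.index) == ["ok"]

    def test_significance_flags(self):
        rng = np.random.default_rng(1)
        control = rng.normal(0, 0.05, size=(2, 10))
        treated = control + np.array([[2.0], [0.5]])  # big and small shifts
        mat, groups = grouped_matrix(control, treated, proteins=["big", "small"])
        res = differential_expression(mat, groups, "control", "treated")
        assert bool(res.loc["big", "significant"])
        assert not bool(res.loc["small", "significant"])  # fc 0.5 below 0.95


class TestImputation:
    def test_knn_complete_matrix_identity(self):
        mat = pd.DataFrame(np.arange(12.0).reshape(3, 4))
        pd.testing.assert_frame_equal(impute_knn(mat), mat)

    def test_knn_duplicate_row_forces_value(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, np.nan], [1.0, 2.0, 3.0, 7.0], [9.0, 9.0, 9.0, 9.0]]
        )
        out = impute_knn(mat, k=1)
        assert out.iloc[0, 3] == 7.0

    def test_knn_mean_of_two_nearest(self):
        mat = pd.DataFrame(
            [
                [1.0, 1.0, 1.0, np.nan],
                [1.0, 1.0, 1.0, 4.0],
                [1.0, 1.0, 1.0, 8.0],
                [10.0, 10.0, 10.0, 10.0],
            ]
        )
        out = impute_knn(mat, k=2)
        assert out.iloc[0, 3] == pytest.approx(6.0)

    def test_knn_observed_cells_untouched(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(6, 5)))
        mat.iloc[0, 0] = np.nan
        out = impute_knn(mat)
        observed = mat.notna().to_numpy()
        assert (out.to_numpy()[observed] == mat.to_numpy()[observed]).all()

    def test_knn_no_overlap_left_missing(self):
        mat = pd.DataFrame(
            [[1.0, np.nan, np.nan], [np.nan, 2.0, 3.0], [np.nan, 4.0, 5.0]]
        )
        out = impute_knn(mat, k=2)
        assert np.isnan(out.iloc[0, 1]) and np.isnan(out.iloc[0, 2])

    def test_min_imputation_fills_global_minimum(self):
        mat = pd.DataFrame([[3.2, np.nan], [np.nan, 5.0]])
        out = impute_min(mat)
        assert out.iloc[0, 1] == 3.2 and out.iloc[1, 0] == 3.2

    def test_min_imputation_all_missing_errors(self):
        with pytest.raises(ValueError):
            impute_min(pd.DataFrame([[np.nan, np.nan]]))


class TestZscore:
    def test_two_point_row(self):
        mat = pd.DataFrame([[0.0, 2.0]])
        out = zscore_rows(mat)
        np.testing.assert_allclose(out.iloc[0], [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_constant_row_undefined(self):
        out = zscore_rows(pd.DataFrame([[5.0, 5.0, 5.0]]))
        assert out.iloc[0].isna().all()

    def test_row_median_zero_after_transform(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(4, 7)))
        out = zscore_rows(mat)
        np.testing.assert_allclose(out.median(axis=1), 0.0, atol=1e-12)


class TestCovariation:
    def test_diagonal_and_symmetry(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(size=(5, 25)))
        res = covariation_matrix(mat, min_cells=10, min_pairwise=10)
        np.testing.assert_allclose(np.diag(res.correlation), 1.0)
        pd.testing.assert_frame_equal(res.correlation, res.correlation.T)
        pd.testing.assert_frame_equal(res.pairwise_n, res.pairwise_n.T)

    def test_exact_linear_pair(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        mat = pd.DataFrame([x, 2 * x + 3, rng.normal(size=30)])
        res = covariation_matrix(mat, min_cells=20, min_pairwise=20)
        assert res.correlation.iloc[0, 1] == pytest.approx(1.0)

    def test_nineteen_shared_cells_excluded(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        a[25:] = np.nan  # observed in cells 0-24 (25 cells)
        b[:6] = np.nan  # observed in cells 6-39 (34 cells); overlap = cells 6-24 = 19
        mat = pd.DataFrame([a, b])
        res = covariation_matrix(mat, min_cells=20, min_pairwise=20)
        assert res.pairwise_n.iloc[0, 1] == 19
        assert np.isnan(res.correlation.iloc[0, 1])

    def test_too_few_qualifying_proteins_errors(self):
        mat = pd.DataFrame(np.random.default_rng(7).normal(size=(3, 10)))
        with pytest.raises(ValueError):
            covariation_matrix(mat, min_cells=20)


class TestClustering:
    def _modules(self, noise=0.0, n_cells=30, seed=8):
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=n_cells)
        rows = [latent + rng.normal(0, noise, n_cells) for _ in range(6)]
        rows += [-latent + rng.normal(0, noise, n_cells) for _ in range(6)]
        return pd.DataFrame(rows, index=[f"m1_{i}" for i in range(6)] + [f"m2_{i}" for i in range(6)])

    def test_noiseless_modules_perfectly_partitioned(self):
        res = covariation_matrix(self._modules(), min_cells=10, min_pairwise=10)
        labels, order = cluster_correlation(res, n_clusters=2)
        m1 = set(labels[labels.index.str.startswith("m1")])
        m2 = set(labels[labels.index.str.startswith("m2")])
        assert len(m1) == 1 and len(m2) == 1 and m1 != m2
        assert len(order) == 12

    def test_singleton_clusters_at_protein_count(self):
        res = covariation_matrix(self._modules(), min_cells=10, min_pairwise=10)
        labels, _ = cluster_correlation(res, n_clusters=12)
        assert labels.nunique() == 12

    def test_too_many_clusters_errors(self):
        res = covariation_matrix(self._modules(), min_cells=10, min_pairwise=10)
        with pytest.raises(ValueError):
            cluster_correlation(res, n_clusters=13)
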
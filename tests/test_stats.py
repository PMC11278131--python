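"""Selection, Hotelling T², PCA profiles, and the small summary arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spatialrqa import packaged_qc_table_path
from spatialrqa.stats import (
    LassoFeatureSelector,
    PCAProfile,
    classification_accuracy,
    hotelling_t2,
    lasso_select,
    load_qc_table,
    pca_summary,
    qc_pass_rate,
    radar_profile,
)


def two_group_data(seed, n=200, p=25, n_informative=5, shift=2.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, p))
    X[:n, :n_informative] += shift
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestLasso:
    def test_full_shrinkage_selects_nothing(self):
        X, y = two_group_data(0)
        sel = LassoFeatureSelector(Cs=[1e-8], seed=0).fit(X, y)
        assert sel.result().n_selected == 0

    def test_informative_columns_recovered(self):
        """5 columns with a 2-SD mean shift vs 20 noise columns, n=200/group."""
        hits = 0
        for seed in range(10):
            X, y = two_group_data(seed)
            res = lasso_select(X, y, seed=seed)
            hits += set(range(5)) <= set(res.selected_indices)
        assert hits >= 9

    def test_permuted_labels_select_almost_nothing(self):
        """Breaking the label-feature link by permutation empties the model
        in most draws (CV-minimum lasso occasionally overfits a handful of
        noise columns, so the bound is on the fraction of quiet draws)."""
        quiet = 0
        for seed in range(20):
            X, y = two_group_data(seed)
            y_perm = np.random.default_rng(1000 + seed).permutation(y)
            res = lasso_select(X, y_perm, seed=seed)
            quiet += res.n_selected <= 2
        assert quiet >= 12

    def test_deterministic_given_seed(self):
        X, y = two_group_data(3)
        a = lasso_select(X, y, seed=7)
        b = lasso_select(X, y, seed=7)
        assert a.selected_indices == b.selected_indices
        assert a.lambda_used == b.lambda_used

    def test_constant_column_dropped_with_warning(self):
        X, y = two_group_data(1)
        X[:, 10] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            res = lasso_select(X, y, seed=0)
        assert 10 not in res.selected_indices

    def test_too_few_rows_rejected(self):
        X, y = two_group_data(0, n=8)
        with pytest.raises(ValueError, match="fold"):
            lasso_select(X, y, n_folds=10)


class TestHotelling:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(40, 5))
        B = A + rng.normal(scale=1e-9, size=A.shape)
        res = hotelling_t2(A, B)
        assert res.t_squared < 1e-10
        assert res.p_value > 0.999999

    def test_one_dim_equals_squared_t_test(self):
        """With p=1 the T² statistic is the squared pooled-variance t."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 40))
            b = rng.normal(loc=rng.normal(), size=rng.integers(5, 40))
            res = hotelling_t2(a[:, None], b[:, None])
            t, p = sps.ttest_ind(a, b, equal_var=True)
            assert res.t_squared == pytest.approx(t**2, abs=1e-10, rel=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(30, 6))
        B = rng.normal(loc=0.3, size=(25, 6))
        base = hotelling_t2(A, B).t_squared
        for _ in range(5):
            M = rng.normal(size=(6, 6)) + 6 * np.eye(6)
            shift = rng.normal(size=6)
            res = hotelling_t2(A @ M + shift, B @ M + shift)
            assert res.t_squared == pytest.approx(base, rel=1e-8)

    def test_insufficient_samples_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="exceed"):
            hotelling_t2(rng.normal(size=(5, 10)), rng.normal(size=(5, 10)))

    def test_singular_covariance_raises_and_shrinkage_recovers(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(30, 3))
        B = rng.normal(size=(30, 3))
        A = np.hstack([A, A[:, :1]])  # duplicated column -> singular pooled cov
        B = np.hstack([B, B[:, :1]])
        with pytest.raises(np.linalg.LinAlgError):
            hotelling_t2(A, B)
        res = hotelling_t2(A, B, shrinkage=0.1)
        assert np.isfinite(res.p_value)

    def test_p_value_decreases_with_t2(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(40, 4))
        results = [
            hotelling_t2(A, rng.normal(loc=mu, size=(40, 4))) for mu in (0.0, 0.5, 1.5)
        ]
        t2s = [r.t_squared for r in results]
        ps = [r.p_value for r in results]
        assert t2s == sorted(t2s)
        assert ps == sorted(ps, reverse=True)


class TestPCA:
    def test_rank_one_data_puts_all_variance_on_pc1(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=8)
        X = np.outer(rng.normal(size=50), direction)
        summary = pca_summary(X + rng.normal(scale=1e-12, size=X.shape))
        assert summary.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-6)

    def test_isotropic_gaussian_splits_evenly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10_000, 3))
        summary = pca_summary(X, n_components=3)
        assert all(0.32 <= r <= 0.35 for r in summary.explained_variance_ratio)

    def test_ratios_non_increasing_and_scores_uncorrelated(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 10)) @ np.diag(np.linspace(3, 0.5, 10))
        summary = pca_summary(X, n_components=5)
        assert (np.diff(summary.explained_variance_ratio) <= 1e-12).all()
        cov = np.cov(summary.scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * np.trace(cov)
        np.testing.assert_allclose(
            np.diag(cov), summary.explained_variance, rtol=1e-10
        )

    def test_component_truncation_warns(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4, 10))
        with pytest.warns(UserWarning, match="truncated"):
            summary = pca_summary(X, n_components=5)
        assert summary.n_components == 3


class TestRadar:
    def test_equal_scores_have_zero_halfwidth(self):
        scores = np.zeros((10, 5))
        prof = PCAProfile(n_components=2)
        rng = np.random.default_rng(0)
        prof.fit(rng.normal(size=(10, 6)))
        summary = prof.summary()
        summary.scores = scores[:, :2]
        table = radar_profile(summary, ["g"] * 10, n_pcs=2)
        assert (table["ci_hi"] == table["ci_lo"]).all()
        assert (table["mean"] == 0).all()

    def test_identical_groups_identical_profiles(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        summary = pca_summary(np.vstack([X, X]), n_components=3)
        table = radar_profile(summary, ["a"] * 40 + ["b"] * 40, n_pcs=3)
        a = table[table.group == "a"].drop(columns=["group", "n"]).reset_index(drop=True)
        b = table[table.group == "b"].drop(columns=["group", "n"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_tiny_group_gets_nan_ci(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 4))
        summary = pca_summary(X, n_components=2)
        table = radar_profile(summary, ["a"] * 10 + ["b"] * 2, n_pcs=2)
        assert table[table.group == "b"]["ci_lo"].isna().all()


class TestQcTable:
    def test_all_pass_table(self):
        table = pd.DataFrame([["P"] * 20], index=["TISSUE"])
        assert qc_pass_rate(table) == 1.0

    def test_single_fail_out_of_twenty(self):
        table = pd.DataFrame([["P"] * 19 + ["F"]], index=["TISSUE"])
        assert qc_pass_rate(table) == 0.95

    def test_malformed_cell_names_location(self):
        table = pd.DataFrame([["P", "X"]], index=["KIDNEY"], columns=["I1", "I2"])
        with pytest.raises(ValueError, match="KIDNEY.*I2"):
            qc_pass_rate(table)

    def test_packaged_table_meets_approval_threshold(self):
        table = load_qc_table(packaged_qc_table_path())
        assert table.shape == (8, 20)
        rate = qc_pass_rate(table)
        assert rate >= 0.80
        assert qc_pass_rate(table.loc[["TESTIS"]]) == 1.0


class TestAccuracy:
    @pytest.mark.parametrize(
        "correct,total,expected",
        [(72, 200, 36.0), (125, 200, 62.5), (120, 200, 60.0), (0, 17, 0.0)],
    )
    def test_percentages(self, correct, total, expected):
        assert classification_accuracy(correct, total) == expected

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            classification_accuracy(5, 0)
        with pytest.raises(ValueError):
            classification_accuracy(-1, 10)
        with pytest.raises(ValueError):
            classification_accuracy(11, 10)
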
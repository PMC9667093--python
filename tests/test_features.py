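"""Feature assembly and the U-test -> Spearman -> LASSO selection cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import connectoml as cm
from connectoml.features import fit_scaler, lasso_lambda_grid
from connectoml.network import ThresholdGrid


class TestAucOverThresholds:
    def test_constant_value(self):
        grid = cm.default_grid()
        assert cm.auc_over_thresholds(np.full(10, 3.0), grid) == pytest.approx(0.45 * 3)

    def test_linear_in_s_is_exact(self):
        grid = cm.default_grid()
        vals = np.asarray(grid.values)
        # trapezoid of f(S)=S equals the exact integral (0.5^2 - 0.05^2)/2
        assert cm.auc_over_thresholds(vals, grid) == pytest.approx(0.12375)

    def test_zeros_and_missing_point(self):
        grid = cm.default_grid()
        assert cm.auc_over_thresholds(np.zeros(10), grid) == 0.0
        with pytest.raises(ValueError):
            cm.auc_over_thresholds(np.zeros(9), grid)


class TestAssembleFeatures:
    def test_feature_count_default_atlas(self):
        assert len(cm.feature_names(160)) == 8877
        assert cm.expected_feature_count(160) == 8877

    def test_feature_count_small_atlas(self):
        assert len(cm.feature_names(10)) == 5 * 10 * 11 + 7 * 11

    def test_constant_metrics_give_045_aucs(self):
        grid = cm.default_grid()
        gvals = np.ones((7, 10))
        nvals = np.ones((5, 10, 4))
        table = cm.assemble_features([(gvals, nvals)], grid)
        aucs = [c for c in table.columns if c.startswith("a")]
        assert np.allclose(table[aucs].to_numpy(), 0.45)
        assert table.shape == (1, cm.expected_feature_count(4))

    def test_incomplete_panel_rejected(self):
        grid = cm.default_grid()
        with pytest.raises(ValueError, match="subject 0"):
            cm.assemble_features([(np.ones((7, 9)), np.ones((5, 10, 4)))], grid)

    def test_names_follow_canonical_scheme(self):
        names = cm.feature_names(42)
        assert "Eglobal_thr0.20" in names
        assert "aEglobal" in names
        assert "DC_thr0.35_node042" in names
        assert "aDC_node042" in names
        assert len(set(names)) == len(names)


@settings(max_examples=20, deadline=None)
@given(
    n_nodes=st.integers(min_value=3, max_value=50),
    n_thr=st.integers(min_value=2, max_value=12),
)
def test_feature_count_closed_form_property(n_nodes, n_thr):
    grid = ThresholdGrid(tuple(round(0.05 + 0.9 * k / n_thr, 6) for k in range(n_thr)))
    assert len(cm.feature_names(n_nodes, grid)) == 5 * n_nodes * (n_thr + 1) + 7 * (n_thr + 1)


class TestStratifiedSplit:
    def test_paper_cohort_counts_round_half_up(self):
        y = np.array([1] * 101 + [0] * 105)
        plan = cm.stratified_split(y, test_frac=0.30, seed=0)
        test_labels = y[plan.test]
        assert (test_labels == 1).sum() == 30  # 30.3 rounds down
        assert (test_labels == 0).sum() == 32  # 31.5 rounds half up
        assert len(np.intersect1d(plan.train, plan.test)) == 0
        assert len(plan.train) + len(plan.test) == 206

    def test_determinism_and_degenerate_fraction(self):
        y = np.array([1] * 6 + [0] * 6)
        a = cm.stratified_split(y, seed=3)
        b = cm.stratified_split(y, seed=3)
        assert np.array_equal(a.test, b.test)
        with pytest.raises(ValueError):
            cm.stratified_split(y, test_frac=0.0)
        with pytest.raises(ValueError):
            cm.stratified_split(np.array([1, 0, 0, 0]), test_frac=0.3)


class TestMannWhitneyScreen:
    def test_exact_enumeration_separated_ranks(self):
        # ranks {1,2,3} vs {4,5,6}: U=0, exact two-sided p = 2/20 = 0.1
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([1, 1, 1, 0, 0, 0])
        p, mask = cm.mannwhitney_screen(X, y, alpha=0.01)
        assert p[0] == pytest.approx(0.1)
        assert not mask[0]

    def test_constant_feature_never_survives(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        y = np.array([1] * 10 + [0] * 10)
        p, mask = cm.mannwhitney_screen(X, y)
        assert p[0] == 1.0 and not mask[0]

    def test_label_like_feature_survives(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 30 + [0] * 30)
        X = (y + rng.normal(0, 0.01, 60))[:, None]
        _, mask = cm.mannwhitney_screen(X, y)
        assert mask[0]


class TestSpearmanPrune:
    def test_duplicate_column_removed_with_rho_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        X = np.column_stack([x, rng.normal(size=50), x])
        kept, log = cm.spearman_prune(X, np.array([0, 1, 2]), ["a", "b", "c"])
        assert kept.tolist() == [0, 1]
        assert log == [("c", "a", pytest.approx(1.0))]

    def test_independent_columns_both_kept(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 2))
        kept, log = cm.spearman_prune(X, np.array([0, 1]), ["a", "b"])
        assert kept.tolist() == [0, 1] and log == []

    def test_correlated_triple_keeps_first_in_order(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=80)
        X = np.column_stack([base + rng.normal(0, 0.1, 80) for _ in range(3)])
        kept, log = cm.spearman_prune(X, np.array([0, 1, 2]), ["a", "b", "c"])
        assert kept.tolist() == [0]
        assert {r[0] for r in log} == {"b", "c"}
        assert all(r[1] == "a" for r in log)


class TestStandardize:
    def test_train_moments_and_test_shift(self):
        rng = np.random.default_rng(4)
        X = rng.normal(5, 3, size=(40, 3))
        scaler = fit_scaler(X)
        Z = scaler.apply(X)
        assert np.allclose(Z.mean(0), 0, atol=1e-12)
        assert np.allclose(Z.std(0), 1, atol=1e-12)
        shifted = scaler.apply(X + 2.0)
        assert np.allclose(shifted.mean(0), 2.0 / X.std(0), atol=1e-9)

    def test_zero_variance_named(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="flat"):
            fit_scaler(X, names=["flat", "ramp"])


class TestLasso:
    def test_huge_lambda_shrinks_everything(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = np.array([1.0] * 15 + [0.0] * 15)
        lam, beta = cm.lasso_select(X, y, ["a", "b", "c", "d"],
                                    lambda_grid=np.array([1e6]), seed=0)
        assert np.all(beta == 0)

    def test_zero_lambda_equals_ols(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(float)
        lam, beta = cm.lasso_select(X, y, list("abc"),
                                    lambda_grid=np.array([1e-10]), seed=0)
        Z = np.column_stack([np.ones(40), X])
        ols = np.linalg.lstsq(Z, y, rcond=None)[0][1:]
        assert np.allclose(beta, ols, atol=1e-4)

    def test_orthonormal_design_soft_threshold(self):
        # with X^T X = I the LASSO solution is soft(beta_ols, lambda/2)
        rng = np.random.default_rng(7)
        A = rng.normal(size=(50, 5))
        Q, _ = np.linalg.qr(A - A.mean(0))
        X = Q  # columns orthonormal, zero mean
        y = np.array([1.0] * 25 + [0.0] * 25)
        rng.shuffle(y)
        lam = 0.1
        _, beta = cm.lasso_select(X, y, list("abcde"),
                                  lambda_grid=np.array([lam]), seed=0)
        ols = X.T @ (y - y.mean())
        soft = np.sign(ols) * np.maximum(np.abs(ols) - lam / 2, 0)
        assert np.allclose(beta, soft, atol=1e-5)

    def test_lambda_max_gives_all_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 6))
        y = (rng.random(30) > 0.5).astype(float)
        grid = lasso_lambda_grid(X, y)
        _, beta = cm.lasso_select(X, y, [f"f{i}" for i in range(6)],
                                  lambda_grid=grid[:1], seed=0)
        assert np.all(beta == 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cm.lasso_select(np.ones((10, 1)), np.zeros(10), ["a"],
                            lambda_grid=np.array([]), seed=0)


class TestCascade:
    def test_selection_nesting_invariant(self, conftest_table=None):
        rng = np.random.default_rng(9)
        y = np.array([1] * 25 + [0] * 25)
        X = rng.normal(size=(50, 40))
        X[:, 0] += y * 2.0
        X[:, 1] = X[:, 0] + rng.normal(0, 0.05, 50)  # collinear partner
        table = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(40)])
        trace = cm.select_features(table, y, seed=1)
        survivors = set(trace.utest_survivors)
        pruned = set(trace.pruned_survivors)
        selected = set(trace.selected_idx)
        assert selected <= pruned <= survivors
        assert 0 in selected  # informative feature found
        assert 1 not in pruned  # collinear later column pruned

    def test_leakage_guard_training_rows_only(self):
        """Deleting the test rows must not change the fitted cascade."""
        rng = np.random.default_rng(10)
        y = np.array([1] * 30 + [0] * 30)
        X = rng.normal(size=(60, 25))
        X[:, 3] += y
        table = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(25)])
        plan = cm.stratified_split(y, seed=2)
        t1 = cm.select_features(table.iloc[plan.train], y[plan.train], seed=2)
        t2 = cm.select_features(
            table.iloc[plan.train].reset_index(drop=True), y[plan.train], seed=2
        )
        assert t1.selected == t2.selected
        assert np.allclose(t1.beta, t2.beta)
        assert t1.lambda_opt == t2.lambda_opt
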
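import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panelflux.matrix import LogExpressionMatrix
from panelflux.predictor import (
    InteractionLassoRegressor,
    apply_coefficient_cutoff,
    build_interaction_features,
    compute_fit_metrics,
    fit_lasso_cv,
    loocv_evaluate,
    predict_rates,
    select_nonzero_genes,
)


class TestFitMetrics:
    def test_perfect_prediction(self):
        m = compute_fit_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.mse, m.rmse, m.mae, m.mre, m.r_squared) == (0, 0, 0, 0, 1)

    def test_hand_computed_example(self):
        m = compute_fit_metrics([2.0, 2.0], [1.0, 2.0])
        assert m.mse == pytest.approx(0.5)
        assert m.rmse == pytest.approx(np.sqrt(0.5))
        assert m.mae == pytest.approx(0.5)
        assert m.mre == pytest.approx(0.5)
        assert m.r_squared == pytest.approx(-1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        p, o = rng.normal(size=20), rng.normal(size=20)
        m = compute_fit_metrics(p, o)
        mse = sum((a - b) ** 2 for a, b in zip(p, o)) / 20
        mae = sum(abs(a - b) for a, b in zip(p, o)) / 20
        mre = sum(abs(a - b) / abs(b) for a, b in zip(p, o)) / 20
        ss_tot = sum((b - o.mean()) ** 2 for b in o)
        r2 = 1 - sum((a - b) ** 2 for a, b in zip(p, o)) / ss_tot
        assert m.mse == pytest.approx(mse)
        assert m.mae == pytest.approx(mae)
        assert m.mre == pytest.approx(mre)
        assert m.r_squared == pytest.approx(r2)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rmse_squared_equals_mse(self, seed):
        rng = np.random.default_rng(seed)
        p, o = rng.normal(size=15), rng.normal(size=15)
        m = compute_fit_metrics(p, o)
        assert m.rmse**2 == pytest.approx(m.mse, rel=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            compute_fit_metrics([1.0], [1.0, 2.0])

    def test_constant_observed_errors(self):
        with pytest.raises(ValueError, match="identical"):
            compute_fit_metrics([1.0, 2.0], [3.0, 3.0])


class TestInteractionFeatures:
    @given(st.integers(1, 25))
    @settings(max_examples=25, deadline=None)
    def test_feature_count_identity(self, k):
        rng = np.random.default_rng(k)
        genes = [f"g{i:02d}" for i in range(k)]
        frame = pd.DataFrame(rng.normal(8, 2, size=(6, k)), columns=genes)
        out = build_interaction_features(frame, genes)
        assert out.shape[1] == k * (k - 1) // 2 + k

    def test_two_gene_example(self):
        frame = pd.DataFrame({"gA": [3.0], "gB": [4.0]})
        out = build_interaction_features(frame, ["gA", "gB"])
        assert list(out.columns) == [("gA", "gB"), ("gA", "gA"), ("gB", "gB")]
        np.testing.assert_allclose(out.iloc[0].to_numpy(), [12.0, 9.0, 16.0])

    def test_single_gene_square_only(self):
        frame = pd.DataFrame({"gA": [3.0, 5.0]})
        out = build_interaction_features(frame, ["gA"])
        assert list(out.columns) == [("gA", "gA")]
        np.testing.assert_allclose(out["gA", "gA"].to_numpy() if ("gA", "gA") in out else out.iloc[:, 0].to_numpy(), [9.0, 25.0])

    def test_duplicate_gene_rejected(self):
        frame = pd.DataFrame({"gA": [3.0]})
        with pytest.raises(ValueError, match="duplicate"):
            build_interaction_features(frame, ["gA", "gA"])

    def test_missing_gene_rejected(self):
        frame = pd.DataFrame({"gA": [3.0]})
        with pytest.raises(KeyError, match="gZ"):
            build_interaction_features(frame, ["gA", "gZ"])


class TestLassoFits:
    def test_huge_penalty_shrinks_to_intercept_only(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        fit = fit_lasso_cv(X, y, seed=0, lambda_=1e9)
        np.testing.assert_allclose(fit.coefficients, 0.0)
        assert fit.intercept == pytest.approx(y.mean())

    def test_zero_penalty_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 4))
        beta = np.array([1.5, -2.0, 0.7, 0.0])
        y = 3.0 + X @ beta
        fit = fit_lasso_cv(X, y, seed=0, lambda_=0)
        # oracle: solve the normal equations directly
        Xd = np.column_stack([np.ones(40), X])
        coefs = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        np.testing.assert_allclose(fit.intercept, coefs[0], atol=1e-8)
        np.testing.assert_allclose(fit.coefficients, coefs[1:], atol=1e-8)

    def test_cv_selects_signal_feature_and_zeroes_noise(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 20))
        y = 2.0 * X[:, 7] + rng.normal(0, 0.05, 60)
        fit = fit_lasso_cv(X, y, seed=1)
        assert abs(fit.coefficients[7]) > 1.0
        others = np.delete(np.abs(fit.coefficients), 7)
        assert np.all(others < 0.1)

    def test_constant_target_errors(self):
        X = np.random.default_rng(0).normal(size=(12, 3))
        with pytest.raises(ValueError, match="constant target"):
            fit_lasso_cv(X, np.ones(12), seed=0)

    def test_nan_features_error(self):
        X = np.ones((12, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fit_lasso_cv(X, np.arange(12.0), seed=0)


class TestGeneSelection:
    def test_all_zero_fit_gives_empty_list(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        fit = fit_lasso_cv(X, rng.normal(size=20), seed=0, lambda_=1e9)
        assert select_nonzero_genes(fit) == []

    def test_threshold_separates_tiny_coefficients(self):
        from panelflux.predictor import LinearFit

        fit = LinearFit(
            feature_names=("a", "b", "c"),
            coefficients=np.array([0.0, 1e-12, 0.3]),
            standardized_coefficients=np.array([0.0, 1e-12, 0.3]),
            intercept=0.0,
            lambda_=0.1,
        )
        assert select_nonzero_genes(fit, tol=1e-8) == ["c"]

    def test_selected_genes_cover_signal_pairs(self, truth, panel):
        matrix, rates = panel
        fit = fit_lasso_cv(matrix.samples_frame(), rates, seed=0)
        genes = set(select_nonzero_genes(fit))
        assert set(truth.signal_genes) <= genes


class TestCoefficientCutoff:
    def test_quantile_threshold_drops_lower_quartile(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = (1.0 * X["a"] + 2.0 * X["b"] + 3.0 * X["c"] + 4.0 * X["d"]).to_numpy()
        fit = fit_lasso_cv(X, y, seed=0, lambda_=1e-3)
        # standardized coefficients ≈ (1, 2, 3, 4) scaled by each column sd;
        # the 25% quantile of non-zero |coefs| with linear interpolation drops
        # everything at or below it
        abs_c = np.abs(fit.standardized_coefficients)
        threshold = np.quantile(abs_c[abs_c > 0], 0.25)
        expected_survivors = {n for n, c in zip("abcd", abs_c) if c > threshold}
        refit = apply_coefficient_cutoff(fit, 0.25, X, y, seed=0)
        assert set(refit.feature_names) == expected_survivors
        assert len(refit.feature_names) == 3

    def test_single_nonzero_coefficient_survives(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = (5.0 * X["a"]).to_numpy() + rng.normal(0, 0.01, 30)
        fit = fit_lasso_cv(X, y, seed=0)
        nz = np.flatnonzero(fit.standardized_coefficients)
        if len(nz) != 1:  # force the degenerate single-survivor situation
            fit.standardized_coefficients[1] = 0.0
            fit.coefficients[1] = 0.0
        refit = apply_coefficient_cutoff(fit, 0.25, X, y, seed=0)
        assert len(refit.feature_names) >= 1

    def test_q_zero_keeps_all_nonzero_features(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = (1.0 * X["a"] + 2.0 * X["b"] + 3.0 * X["c"]).to_numpy()
        fit = fit_lasso_cv(X, y, seed=0, lambda_=1e-3)
        refit = apply_coefficient_cutoff(fit, 0.0, X, y, seed=0)
        nonzero = [n for n, c in zip(fit.feature_names, fit.standardized_coefficients) if c != 0]
        assert set(refit.feature_names) == set(nonzero)

    def test_all_zero_coefficients_error(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = rng.normal(size=20)
        fit = fit_lasso_cv(X, y, seed=0, lambda_=1e9)
        with pytest.raises(ValueError, match="all coefficients are zero"):
            apply_coefficient_cutoff(fit, 0.25, X, y, seed=0)


class TestLoocv:
    def test_intercept_only_model_has_nonpositive_r2(self):
        class MeanRegressor(InteractionLassoRegressor):
            def fit(self, X, y):
                self.mean_ = float(np.mean(y))
                return self

            def predict(self, X):
                frame = self._gene_frame(X)
                return np.full(len(frame), self.mean_)

        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        y = rng.normal(size=15)
        preds, metrics = loocv_evaluate(X, y, mode="nested", estimator=MeanRegressor())
        # each prediction is the training-fold mean
        for i in range(15):
            assert preds.iloc[i] == pytest.approx(np.delete(y, i).mean())
        assert metrics.r_squared <= 0

    def test_unknown_mode_rejected(self, panel):
        matrix, rates = panel
        with pytest.raises(ValueError, match="unknown LOOCV mode"):
            loocv_evaluate(matrix.samples_frame(), rates, mode="bootstrap")

    def test_nested_mode_runs_on_small_panel(self):
        from panelflux.simulate import generate_cell_line_panel, make_ground_truth

        truth = make_ground_truth(n_genes=40, n_pairs=1, seed=13)
        matrix, rates = generate_cell_line_panel(40, 16, truth, seed=14)
        est = InteractionLassoRegressor(order=2, cutoff_q=0.25, random_state=0)
        preds, metrics = loocv_evaluate(
            matrix.samples_frame(), rates, mode="nested", seed=0, estimator=est
        )
        assert len(preds) == 16
        assert np.isfinite(metrics.r_squared)


class TestPredictRates:
    def test_intercept_only_predicts_constant(self, noise_free_cohort):
        est = InteractionLassoRegressor(order=2)
        est.genes_ = ["G0000"]
        from panelflux.predictor import LinearFit

        est.final_fit_ = LinearFit(
            feature_names=(("G0000", "G0000"),),
            coefficients=np.array([0.0]),
            standardized_coefficients=np.array([0.0]),
            intercept=0.042,
            lambda_=0.1,
        )
        est.features_ = est.final_fit_.feature_names
        preds = predict_rates(est, noise_free_cohort.rnaseq_matrix)
        np.testing.assert_allclose(preds["rate"].to_numpy(), 0.042)
        assert not preds["negative"].any()

    def test_missing_gene_listed_in_error(self, panel):
        matrix, rates = panel
        est = InteractionLassoRegressor(order=2, random_state=0)
        est.fit(matrix.samples_frame(), rates)
        reduced = matrix.subset_genes([g for g in matrix.gene_ids if g != est.genes_[0]])
        with pytest.raises(KeyError, match=est.genes_[0]):
            predict_rates(est, reduced)

    def test_sample_order_equivariance(self, panel):
        matrix, rates = panel
        est = InteractionLassoRegressor(order=2, random_state=0)
        est.fit(matrix.samples_frame(), rates)
        preds = predict_rates(est, matrix)
        perm = list(matrix.sample_ids[::-1])
        preds_perm = predict_rates(est, matrix.subset_samples(perm))
        pd.testing.assert_frame_equal(preds.loc[perm], preds_perm)
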
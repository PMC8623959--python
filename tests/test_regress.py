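"""Fold construction, SVR training/prediction, metrics and the log baseline."""

import numpy as np
import pandas as pd
import pytest

from lrfa.features import OBJECTIVE_COLUMN
from lrfa.regress import (
    SVRConfig,
    assign_folds,
    evaluate,
    fit_log_baseline,
    load_model,
    loocv,
    predict,
    predict_from_log_baseline,
    save_model,
    train_svr,
)

SMALL_GRID = SVRConfig(
    epsilon_grid=(2.0**-8, 2.0**-4, 2.0**-2),
    C_grid=(1.0, 16.0, 256.0),
    gamma_grid=(2.0**-6, 2.0**-3, 1.0),
    rng_seed=0,
)


def _linear_table(n=30, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.linspace(0.1, 3.0, n)
    return pd.DataFrame(
        {"x": x + rng.normal(0, noise, n), OBJECTIVE_COLUMN: x}
    )


class TestAssignFolds:
    def test_hand_worked_example(self):
        folds = assign_folds([0.1, 0.5, 1.0, 2.0, 3.0])
        # extremes 0.1 and 3.0 in fold 1; sorted middle 0.5, 1, 2 -> folds 1, 2, 3
        np.testing.assert_array_equal(folds, [1, 1, 2, 3, 1])

    def test_56_measurements_give_20_18_18(self):
        rng = np.random.default_rng(0)
        torques = rng.uniform(0.06, 3.0, 56)
        folds = assign_folds(torques)
        sizes = np.bincount(folds)[1:]
        np.testing.assert_array_equal(sorted(sizes, reverse=True), [20, 18, 18])

    @pytest.mark.parametrize("n", [5, 11, 23, 57])
    def test_every_fold_nonempty_and_extremes_in_fold_1(self, n):
        rng = np.random.default_rng(n)
        torques = rng.uniform(0.06, 3.0, n)
        folds = assign_folds(torques)
        assert set(folds) == {1, 2, 3}
        assert folds[np.argmin(torques)] == 1
        assert folds[np.argmax(torques)] == 1
        sizes = np.bincount(folds)[1:]
        assert sizes.max() - sizes.min() <= 3  # triplet remainder + the 2 extremes

    def test_torque_ties_keep_input_order(self):
        folds = assign_folds([0.1, 1.0, 1.0, 1.0, 3.0])
        np.testing.assert_array_equal(folds, [1, 1, 2, 3, 1])

    def test_all_equal_torques_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            assign_folds([1.0] * 6)

    def test_too_few_measurements_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            assign_folds([0.1, 0.2, 0.3, 0.4])


class TestTrainPredict:
    def test_noiseless_linear_relation_is_learned(self):
        table = _linear_table()
        model = train_svr(table, ["x"], SMALL_GRID)
        assert model.training_r2 >= 0.99
        preds = predict(model, table)
        r2 = evaluate(table[OBJECTIVE_COLUMN].to_numpy(), preds).r2
        assert r2 >= 0.99

    def test_single_triple_grid_passes_through(self):
        cfg = SVRConfig(epsilon_grid=(0.125,), C_grid=(4.0,), gamma_grid=(0.5,))
        model = train_svr(_linear_table(), ["x"], cfg)
        assert (model.epsilon, model.C, model.gamma) == (0.125, 4.0, 0.5)

    def test_duplicated_rows_get_identical_predictions(self):
        table = _linear_table()
        model = train_svr(table, ["x"], SMALL_GRID)
        row = table.iloc[[3]]
        duplicated = pd.concat([row, row])
        preds = predict(model, duplicated)
        assert preds[0] == preds[1]

    def test_missing_columns_listed_in_error(self):
        model = train_svr(_linear_table(), ["x"], SMALL_GRID)
        with pytest.raises(ValueError, match="x"):
            predict(model, pd.DataFrame({"y": [1.0]}))

    def test_extrapolated_prediction_is_finite_and_flagged(self):
        table = _linear_table()
        model = train_svr(table, ["x"], SMALL_GRID)
        far = pd.DataFrame({"x": [50.0]})
        with pytest.warns(RuntimeWarning, match="extrapolation"):
            preds = predict(model, far)
        assert np.isfinite(preds).all()

    def test_zero_variance_objective_rejected(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], OBJECTIVE_COLUMN: [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="zero variance"):
            train_svr(table, ["x"], SMALL_GRID)

    def test_model_roundtrip_through_json(self, tmp_path):
        table = _linear_table(noise=0.05, seed=2)
        model = train_svr(table, ["x"], SMALL_GRID)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_allclose(predict(loaded, table), predict(model, table), rtol=1e-12)


class TestEvaluate:
    def test_perfect_prediction(self):
        report = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert report.r2 == pytest.approx(1.0)
        assert report.pearson_r == pytest.approx(1.0)
        assert report.mse == 0.0
        assert report.frac_within_20pct == 1.0

    def test_hand_worked_band_counts(self):
        # |1.1-1| = 0.1 <= 0.2; |2.5-2| = 0.5 > 0.4
        report = evaluate([1.0, 2.0], [1.1, 2.5])
        assert report.n_within == 1
        assert report.n_total == 2

    def test_16_of_18_gives_889_percent(self):
        true = np.linspace(1.0, 2.7, 18)
        predicted = true.copy()
        predicted[0] *= 1.5
        predicted[-1] *= 0.5
        report = evaluate(true, predicted)
        assert report.n_within == 16
        assert report.frac_within_20pct == pytest.approx(16 / 18)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            evaluate([1.0, 1.0], [1.0, 2.0])

    def test_rescaling_preserves_r_and_band_fraction_but_not_mse(self):
        rng = np.random.default_rng(4)
        true = rng.uniform(0.5, 3.0, 20)
        predicted = true * (1 + rng.normal(0, 0.15, 20))
        base = evaluate(true, predicted)
        scaled = evaluate(5.0 * true, 5.0 * predicted)
        assert scaled.pearson_r == pytest.approx(base.pearson_r, rel=1e-12)
        assert scaled.frac_within_20pct == base.frac_within_20pct
        assert scaled.mse == pytest.approx(25.0 * base.mse, rel=1e-12)


class TestLogBaseline:
    def test_exact_logarithmic_data_recovered(self):
        torques = np.array([0.1, 0.3, 0.8, 1.5, 3.0])
        freqs = 2000.0 * np.log(torques) + 6000.0
        a, b, r2 = fit_log_baseline(torques, freqs)
        assert a == pytest.approx(2000.0)
        assert b == pytest.approx(6000.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_frequencies_give_zero_slope_and_r2(self):
        a, _, r2 = fit_log_baseline([0.5, 1.0, 2.0], [5000.0, 5000.0, 5000.0])
        assert a == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_torque_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_log_baseline([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])

    def test_inversion_roundtrip(self):
        torques = np.array([0.2, 0.7, 1.9])
        freqs = 1500.0 * np.log(torques) + 7000.0
        a, b, _ = fit_log_baseline(torques, freqs)
        np.testing.assert_allclose(predict_from_log_baseline(a, b, freqs), torques, rtol=1e-9)


class TestLoocv:
    def test_three_rows_give_three_points(self):
        table = pd.DataFrame({"x": [0.1, 1.0, 2.0], OBJECTIVE_COLUMN: [0.1, 1.0, 2.0]})
        cfg = SVRConfig(epsilon_grid=(0.01,), C_grid=(10.0,), gamma_grid=(1.0,))
        report = loocv(table, ["x"], cfg)
        assert len(report.points) == 3

    def test_learnable_interior_points_predicted_well(self):
        table = _linear_table(n=25)
        report = loocv(table, ["x"], SMALL_GRID)
        interior = report.points.iloc[1:-1]
        errors = np.abs(interior.predicted_nm - interior.true_nm)
        assert np.median(errors) < 0.05
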
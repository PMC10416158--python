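"""Metrics and permutation importance vs independent library oracles."""

import numpy as np
import pandas as pd
import pytest

import gonipose as gp


class TestScore:
    def test_perfect_prediction(self):
        y = np.array([10.0, 50.0, 90.0, 130.0])
        rep = gp.score(y, y)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.mape_percent == pytest.approx(0.0)
        assert rep.mae == pytest.approx(0.0)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_mean_model_has_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        rep = gp.score(y, np.full(4, y.mean()), mape="skip")
        assert rep.r2 == pytest.approx(0.0)

    def test_worked_percentage_example(self):
        rep = gp.score([100.0, 200.0], [110.0, 190.0])
        assert rep.mape_percent == pytest.approx(7.5)
        assert rep.mae == pytest.approx(10.0)

    def test_zero_truth_makes_mape_undefined(self):
        with pytest.raises(gp.MetricUndefinedError):
            gp.score([0.0, 10.0], [1.0, 9.0])
        rep = gp.score([0.0, 10.0], [1.0, 9.0], mape="auto")
        assert rep.mape_percent is None
        assert any("MAPE undefined" in n for n in rep.notes)

    def test_matches_sklearn_oracles_on_random_vectors(self, rng):
        from sklearn.metrics import (
            mean_absolute_error,
            mean_absolute_percentage_error,
            r2_score,
        )

        for _ in range(20):
            y = rng.uniform(5.0, 160.0, size=200)
            p = y + rng.normal(0.0, 10.0, size=200)
            rep = gp.score(y, p)
            assert rep.r2 == pytest.approx(r2_score(y, p), abs=1e-10)
            assert rep.mae == pytest.approx(mean_absolute_error(y, p), abs=1e-10)
            assert rep.mape_percent == pytest.approx(
                100.0 * mean_absolute_percentage_error(y, p), abs=1e-8
            )
            assert rep.pearson_r == pytest.approx(np.corrcoef(y, p)[0, 1], abs=1e-12)

    def test_report_serialization_roundtrip(self):
        rep = gp.score([10.0, 20.0, 30.0], [11.0, 19.0, 31.0])
        text = rep.to_text()
        assert "r2:" in text and "mape_percent:" in text
        assert rep.to_dict()["n"] == 3


class TestCorrelations:
    def test_exact_positive_and_negative(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0]})
        df["same"] = df["t"]
        df["anti"] = -df["t"]
        corr = gp.feature_target_correlations(df, "t", features=["same", "anti"])
        assert corr["same"] == pytest.approx(1.0)
        assert corr["anti"] == pytest.approx(-1.0)

    def test_constant_column_flagged_not_nan(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
        corr = gp.feature_target_correlations(df, "t", features=["const"])
        assert corr["const"] is None


class _IdentityModel:
    def predict(self, X):
        return X["signal"].to_numpy(dtype=float)


class TestPermutationImportance:
    def test_null_feature_importance_within_noise_of_zero(self, rng):
        n = 400
        X = pd.DataFrame({"signal": rng.normal(size=n), "noise": rng.normal(size=n)})
        y = X["signal"].to_numpy()
        imp = gp.permutation_importance(_IdentityModel(), X, y, n_repeats=20, seed=0)
        mean, sd = imp["noise"]
        assert abs(mean) <= 3 * max(sd, 1e-12)

    def test_identity_model_loses_all_r2_when_shuffled(self, rng):
        n = 400
        X = pd.DataFrame({"signal": rng.normal(size=n)})
        y = X["signal"].to_numpy()
        imp = gp.permutation_importance(_IdentityModel(), X, y, n_repeats=10, seed=0)
        mean, _ = imp["signal"]
        # shuffling the lone perfect predictor doubles the residual variance,
        # so r2 falls from 1 to about -1 and the drop is ~2
        assert mean == pytest.approx(2.0, abs=0.2)

    def test_deterministic_given_seed(self, small_noisy_table):
        X = small_noisy_table[list(gp.STAGE1_FEATURES)]
        y = small_noisy_table["true_abduction_deg"]
        model = gp.train_regressor(X, y, gp.RegressorSpec(family="linear"))
        a = gp.permutation_importance(model, X, y, n_repeats=3, seed=9)
        b = gp.permutation_importance(model, X, y, n_repeats=3, seed=9)
        assert a == b

    def test_collinear_duplicate_shrinks_importance(self, rng):
        n = 500
        base = rng.normal(size=n)
        y = 2.0 * base + rng.normal(0.0, 0.1, size=n)
        X1 = pd.DataFrame({"f": base})
        X2 = pd.DataFrame({"f": base, "f_copy": base})
        m1 = gp.train_regressor(X1, y, gp.RegressorSpec(family="linear"))
        m2 = gp.train_regressor(X2, y, gp.RegressorSpec(family="linear"))
        solo = gp.permutation_importance(m1, X1, y, n_repeats=10, seed=0)["f"][0]
        dup = gp.permutation_importance(m2, X2, y, n_repeats=10, seed=0)
        assert dup["f"][0] <= solo + 1e-9
        assert dup["f_copy"][0] <= solo + 1e-9

    def test_matches_sklearn_permutation_importance(self, small_noisy_table):
        from sklearn.inspection import permutation_importance as sk_imp

        X = small_noisy_table[list(gp.STAGE1_FEATURES)]
        y = small_noisy_table["true_abduction_deg"].to_numpy()
        model = gp.train_regressor(X, y, gp.RegressorSpec(family="linear"))
        ours = gp.permutation_importance(model, X, y, n_repeats=30, seed=0)
        theirs = sk_imp(model.estimator, X, y, scoring="r2", n_repeats=30, random_state=0)
        for i, name in enumerate(X.columns):
            assert ours[name][0] == pytest.approx(
                theirs.importances_mean[i], abs=3 * (ours[name][1] + theirs.importances_std[i]) + 1e-6
            )
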
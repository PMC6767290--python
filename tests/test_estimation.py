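"""SVR / LR fitting, LOTO fold structure, and fill-ratio conditioning."""

import numpy as np
import pytest

import siptrack as st
from siptrack.io_types import ValidationError


class TestFit:
    def test_flat_target_predicted_within_epsilon(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.full(30, 7.0)
        spec = st.ModelSpec(model="svm", kernel="medium", epsilon_tube=0.1)
        model = st.fit(spec, X, y)
        np.testing.assert_allclose(model.predict(X), 7.0, atol=0.1 + 1e-6)

    def test_linear_kernel_recovers_exact_line(self, rng):
        """y = 2 * x1 with ample slack: prediction at x1 = 3 is 6 within 0.1."""
        x1 = np.linspace(-2, 2, 20)
        X = np.column_stack([x1, rng.normal(0, 0.01, 20)])
        y = 2.0 * x1
        spec = st.ModelSpec(model="svm", kernel="linear", box_constraint=100.0, epsilon_tube=0.01)
        model = st.fit(spec, X, y)
        pred = model.predict(np.array([[3.0, 0.0]]))
        assert pred[0] == pytest.approx(6.0, abs=0.1)

    def test_medium_kernel_scale_stored_and_used(self):
        spec = st.ModelSpec(model="svm", kernel="medium")
        assert spec.effective_kernel_scale == 5.7
        X = np.random.default_rng(0).normal(size=(10, 3))
        model = st.fit(spec, X, np.arange(10.0))
        assert model.regressor.gamma == pytest.approx(1 / 5.7**2)
        assert st.ModelSpec(model="svm", kernel="coarse").effective_kernel_scale == 23.0

    def test_zero_variance_feature_dropped_with_warning(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            model = st.fit(st.ModelSpec(), X, rng.normal(size=20))
        assert model.kept.tolist() == [True, False]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError, match="2 training rows"):
            st.fit(st.ModelSpec(), np.ones((1, 3)), np.ones(1))


class TestSingleFactorLR:
    def test_exact_line(self):
        model = st.fit_lr_single(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0]))
        assert model.regressor.b0 == pytest.approx(0.0, abs=1e-12)
        assert model.regressor.b1 == pytest.approx(2.0)

    def test_constant_response_zero_slope(self):
        model = st.fit_lr_single(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))
        assert model.regressor.b1 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        f = rng.normal(size=50)
        y = rng.normal(size=50)
        model = st.fit_lr_single(f, y)
        # closed-form normal equations
        A = np.column_stack([np.ones(50), f])
        b0, b1 = np.linalg.solve(A.T @ A, A.T @ y)
        assert model.regressor.b0 == pytest.approx(b0, abs=1e-9)
        assert model.regressor.b1 == pytest.approx(b1, abs=1e-9)

    def test_zero_variance_feature_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            st.fit_lr_single(np.full(10, 2.0), np.arange(10.0))


class TestConditionTrainingSet:
    def test_nearest_single(self):
        idx = st.condition_training_set(np.array([0.1, 0.5, 0.9]), 0.55, k=1)
        assert idx.tolist() == [1]

    def test_k_equals_n_returns_all(self):
        idx = st.condition_training_set(np.array([0.1, 0.5, 0.9]), 0.2, k=3)
        assert sorted(idx.tolist()) == [0, 1, 2]

    def test_matches_sort_prefix_oracle(self, rng):
        fr = rng.uniform(0, 1, 1000)
        q = 0.42
        got = set(st.condition_training_set(fr, q, k=150).tolist())
        expected = set(np.argsort(np.abs(fr - q), kind="stable")[:150].tolist())
        assert got == expected

    def test_ties_break_by_row_order(self):
        fr = np.array([0.4, 0.6, 0.4, 0.6])
        idx = st.condition_training_set(fr, 0.5, k=2)
        assert idx.tolist() == [0, 1]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            st.condition_training_set(np.array([0.5]), 0.5, k=2)


class TestAppendFillRatio:
    def test_adds_one_column_and_records_source(self, rng):
        X = rng.normal(size=(10, 33))
        fr = rng.uniform(0, 1, 10)
        X2, prov = st.append_fill_ratio_feature(X, fr, source="truth")
        assert X2.shape == (10, 34)
        np.testing.assert_array_equal(X2[:, -1], fr)
        assert prov == {"fill_ratio_source": "truth"}

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError, match="rows"):
            st.append_fill_ratio_feature(rng.normal(size=(10, 3)), np.ones(9), "truth")


def _toy_dataset(rng, n_trials=3, drinks=4):
    X, y, trials, drink = [], [], [], []
    for t in range(n_trials):
        for d in range(drinks):
            X.append(rng.normal(size=5))
            y.append(rng.uniform(10, 100))
            trials.append(f"T{t}")
            drink.append(d + 1)
    return np.array(X), np.array(y), np.array(trials), np.array(drink)


class TestLOTO:
    def test_one_fold_per_trial_heldout_excluded(self, rng):
        X, y, trials, drink = _toy_dataset(rng)
        folds = st.loto_evaluate(st.ModelSpec(), X, y, trials, drink)
        assert len(folds) == 3
        for f in folds:
            assert f.held_out not in f.train_groups
            assert len(f.train_groups) == 2
            assert len(f.y_pred) == 4

    def test_single_trial_rejected(self, rng):
        X, y, trials, drink = _toy_dataset(rng, n_trials=1)
        with pytest.raises(ValidationError, match="at least 2"):
            st.loto_evaluate(st.ModelSpec(), X, y, trials, drink)

    def test_duplicating_a_trial_only_changes_other_folds_training(self, rng):
        X, y, trials, drink = _toy_dataset(rng)
        X2 = np.vstack([X, X[trials == "T2"]])
        y2 = np.concatenate([y, y[trials == "T2"]])
        trials2 = np.concatenate([trials, np.repeat("T2b", 4)])
        drink2 = np.concatenate([drink, drink[trials == "T2"]])
        folds = {f.held_out: f for f in st.loto_evaluate(st.ModelSpec(), X2, y2, trials2, drink2)}
        assert set(folds) == {"T0", "T1", "T2", "T2b"}
        # every other fold's training set gained the duplicated trial
        assert "T2b" in folds["T0"].train_groups

    def test_standardization_is_fold_specific(self, rng):
        X, y, trials, drink = _toy_dataset(rng)
        folds = st.loto_evaluate(st.ModelSpec(), X, y, trials, drink)
        means = [f.standardization_mean for f in folds]
        assert not np.allclose(means[0], means[1])
        assert not np.allclose(means[1], means[2])

    def test_deterministic(self, rng):
        X, y, trials, drink = _toy_dataset(rng)
        a = st.loto_evaluate(st.ModelSpec(), X, y, trials, drink)
        b = st.loto_evaluate(st.ModelSpec(), X, y, trials, drink)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.y_pred, fb.y_pred)

    def test_append_strategy_uses_34_features(self, rng):
        X, y, trials, drink = _toy_dataset(rng)
        fr = rng.uniform(0, 1, len(y))
        folds = st.loto_evaluate(
            st.ModelSpec(fr_source="truth"), X, y, trials, drink,
            fr=fr, fr_query=fr, strategy="append",
        )
        assert len(folds[0].standardization_mean) == 6  # 5 features + fill ratio

    def test_partition_strategy_respects_k(self, rng):
        X, y, trials, drink = _toy_dataset(rng, n_trials=4)
        fr = rng.uniform(0, 1, len(y))
        folds = st.loto_evaluate(
            st.ModelSpec(), X, y, trials, drink,
            fr=fr, fr_query=fr, strategy="partition", k_nearest=6,
        )
        assert len(folds) == 4 and all(len(f.y_pred) == 4 for f in folds)


class TestMultiTargetBenefit:
    def test_true_fill_ratio_feature_improves_volume_mape(self, cohort_df):
        """Appending the ground-truth fill ratio helps volume estimation.

        The drink motion signature confounds volume with fill level, so
        giving the model the fill level should reduce error on a cohort
        where both influence the signal.
        """
        import warnings

        spec = st.ModelSpec(target="volume", model="svm", kernel="coarse")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, base = st.evaluate_spec(cohort_df, spec)
            _, aug = st.evaluate_spec(
                cohort_df,
                st.ModelSpec(target="volume", model="svm", kernel="coarse", fr_source="truth"),
                strategy="append",
            )
        assert aug.pooled_mape < base.pooled_mape
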
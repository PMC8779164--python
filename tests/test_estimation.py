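"""Block-relaxation fitting: convergence, monotonicity, reproducibility,
learning-rate selection and parameter recovery."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from tensorreg import (
    FitConfig,
    MultinomialTensorRegression,
    parameter_recovery_report,
    tune_learning_rate,
)
from tensorreg.synthetic import SyntheticScenario, generate, stratified_split


class TestFitConfig:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            FitConfig(epsilon=0)
        with pytest.raises(ValueError):
            FitConfig(inner_steps=0)
        with pytest.raises(ValueError):
            FitConfig(mode="newton")

    def test_dict_round_trip(self):
        cfg = FitConfig(learning_rate=0.05, seed=3)
        assert FitConfig.from_dict(cfg.to_dict()) == cfg


class TestBlockRelaxation:
    def test_separable_data_reaches_perfect_training_accuracy(self, small_planted):
        _, data, _ = small_planted
        res = MultinomialTensorRegression(data).fit(seed=11)
        assert res.converged
        assert np.mean(res.predict() == data.label_indices) == 1.0

    def test_loglik_trace_monotone_within_tolerance(self, small_planted):
        _, data, _ = small_planted
        res = MultinomialTensorRegression(data).fit(seed=11)
        diffs = np.diff(res.loglik_trace)
        assert diffs.min() > -1e-3

    def test_convergence_criterion_is_loglik_difference(self, small_planted):
        _, data, _ = small_planted
        res = MultinomialTensorRegression(data).fit(seed=11)
        assert res.converged
        assert abs(res.loglik_trace[-1] - res.loglik_trace[-2]) < res.config.epsilon

    def test_reproducible_given_seed(self, small_planted):
        _, data, _ = small_planted
        r1 = MultinomialTensorRegression(data).fit(seed=4, max_outer_iters=5)
        r2 = MultinomialTensorRegression(data).fit(seed=4, max_outer_iters=5)
        assert np.array_equal(r1.loglik_trace, r2.loglik_trace)
        for t1, t2 in zip(r1.params.cp, r2.params.cp):
            for f1, f2 in zip(t1.factors, t2.factors):
                assert np.array_equal(f1, f2)

    def test_null_data_with_intercepts_approaches_intercept_only_optimum(self):
        scenario = SyntheticScenario(
            shape=(3, 4, 3), amplitude=0.0, n_per_class=(100, 100, 300), seed=5
        )
        data, _ = generate(scenario)
        train, test = stratified_split(data, 0.2, seed=5)
        res = MultinomialTensorRegression(train, use_intercepts=True).fit(seed=0)
        phat = train.class_counts / train.n
        opt = train.n * np.sum(phat * np.log(phat))
        assert res.llf >= opt - 1.0          # at least the intercept-only fit
        assert res.llf <= opt - 0.1 * opt    # but not a degenerate perfect fit
        # held-out accuracy approaches the majority-class frequency
        pa = np.mean(res.predict(test) == test.label_indices)
        assert abs(pa - phat.max()) <= 0.1

    def test_null_data_without_intercepts_bounded_by_uniform_loglik(self):
        scenario = SyntheticScenario(
            shape=(3, 4, 3), amplitude=0.0, n_per_class=(100, 100, 300), seed=5
        )
        data, _ = generate(scenario)
        res = MultinomialTensorRegression(data).fit(seed=0)
        assert res.llf >= data.n * np.log(1 / 3)

    def test_joint_mode_agrees_with_block_mode(self, small_planted):
        _, data, _ = small_planted
        rb = MultinomialTensorRegression(data).fit(seed=2)
        rj = MultinomialTensorRegression(data).fit(seed=2, mode="joint")
        # both reach essentially perfect fits on separable data
        assert np.mean(rb.predict() == data.label_indices) == 1.0
        assert np.mean(rj.predict() == data.label_indices) == 1.0

    def test_two_class_fit_correlates_with_vectorized_logistic_oracle(self):
        scenario = SyntheticScenario(
            shape=(3, 4, 3), n_per_class=1000, K=2, amplitude=1.0, seed=3
        )
        data, _ = generate(scenario)
        res = MultinomialTensorRegression(data).fit(seed=0)
        B = res.params.cp[0].materialize().ravel()
        Xv = data.images.reshape(data.n, -1)
        oracle = LogisticRegression(C=1e6, fit_intercept=False, max_iter=5000)
        oracle.fit(Xv, (data.label_indices == 0).astype(int))
        corr = np.corrcoef(B, oracle.coef_.ravel())[0, 1]
        assert corr > 0.8

    def test_summary_reports_fit(self, small_planted):
        _, data, _ = small_planted
        res = MultinomialTensorRegression(data).fit(seed=11)
        text = res.summary()
        assert "Log-likelihood" in text
        assert f"{data.n}" in text
        assert "Training PA" in text


class TestLearningRateTuning:
    def test_single_value_grid(self, small_planted):
        _, data, _ = small_planted
        rate = tune_learning_rate(
            data, FitConfig(seed=0, max_outer_iters=10), [0.02], n_folds=2
        )
        assert rate == 0.02

    def test_absurd_rate_loses(self, small_planted):
        _, data, _ = small_planted
        rate = tune_learning_rate(
            data, FitConfig(seed=0, max_outer_iters=100), [1e-2, 1e6], n_folds=4
        )
        assert rate == 1e-2

    def test_deterministic_given_seed(self, small_planted):
        _, data, _ = small_planted
        args = (data, FitConfig(seed=9, max_outer_iters=10), [0.005, 0.02], 2)
        assert tune_learning_rate(*args) == tune_learning_rate(*args)

    def test_impossible_stratification_errors(self, small_planted):
        _, data, _ = small_planted
        with pytest.raises(ValueError, match="stratify"):
            tune_learning_rate(data, FitConfig(), [0.01], n_folds=data.n)


class TestRecoveryReport:
    def test_identical_params_give_cosine_one(self, small_planted):
        _, _, truth = small_planted
        rep = parameter_recovery_report(truth, truth)
        assert rep.cosines == pytest.approx([1.0, 1.0])
        assert rep.surface_correlations == pytest.approx([1.0, 1.0])

    def test_sign_flip_preserves_absolute_cosine(self, small_planted):
        _, _, truth = small_planted
        flipped = truth.copy()
        for t in flipped.cp:
            t.factors[0] *= -1
        rep = parameter_recovery_report(truth, flipped)
        assert rep.cosines == pytest.approx([-1.0, -1.0])
        assert rep.min_abs_cosine == pytest.approx(1.0)

    def test_frame_output(self, small_planted):
        _, _, truth = small_planted
        df = parameter_recovery_report(truth, truth).to_frame()
        assert list(df.columns) == ["class", "cosine", "abs_cosine", "surface_corr"]
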
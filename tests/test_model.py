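"""Linear predictors, softmax probabilities, likelihood and gradient."""

import math

import numpy as np
import pytest
from scipy.special import expit

from tensorreg.model import (
    Dataset,
    ModelParams,
    MultinomialTensorRegression,
    class_probabilities,
    count_free_parameters,
    linear_predictors,
    log_likelihood,
    log_likelihood_gradient,
    predict_labels,
    softmax_probabilities,
)
from tensorreg.tensor_algebra import CPTensor


def random_dataset(rng, shape=(3, 2, 2), n=6, K=3, covariates=False):
    X = rng.normal(size=(n,) + shape)
    y = rng.integers(0, K, size=n)
    y[:K] = np.arange(K)  # every class present
    Z = rng.normal(size=(n, 2)) if covariates else None
    return Dataset.from_arrays(X, y, covariates=Z)


def random_params(rng, shape=(3, 2, 2), K=3, rank=1, intercepts=False, p=0):
    cp = [
        CPTensor([rng.normal(size=(d, rank)) for d in shape])
        for _ in range(K - 1)
    ]
    return ModelParams(
        cp=cp,
        reference_class=K - 1,
        intercepts=rng.normal(size=K - 1) if intercepts else None,
        covariate_coefs=rng.normal(size=(K - 1, p)) if p else None,
    )


class TestLinearPredictor:
    def test_zero_params(self, rng):
        data = random_dataset(rng)
        params = ModelParams.zeros((3, 2, 2), K=3)
        assert np.array_equal(linear_predictors(params, data.images), np.zeros((6, 3)))

    def test_indicator_tensor_reads_one_voxel(self):
        X = np.zeros((2, 2, 2))
        X[0, 0, 0] = 3.0
        params = ModelParams(
            cp=[CPTensor.from_vectors(([1, 0], [1, 0], [1, 0]))], reference_class=1
        )
        eta = linear_predictors(params, X)
        assert np.array_equal(eta, [3.0, 0.0])

    def test_matches_materialized_dot(self, rng):
        data = random_dataset(rng)
        params = random_params(rng, rank=2)
        eta = linear_predictors(params, data.images)
        for i in range(data.n):
            for m, k in enumerate(params.nonreference_classes):
                expected = np.sum(params.cp[m].materialize() * data.images[i])
                assert eta[i, k] == pytest.approx(expected, rel=1e-10)
        assert np.all(eta[:, 2] == 0)

    def test_shape_mismatch(self, rng):
        params = random_params(rng)
        with pytest.raises(ValueError, match="shape"):
            linear_predictors(params, np.zeros((4, 2, 2)))


class TestProbabilities:
    def test_symmetry_at_zero(self, rng):
        data = random_dataset(rng)
        params = ModelParams.zeros((3, 2, 2), K=3)
        mu = class_probabilities(params, data)
        assert np.allclose(mu, 1 / 3)

    def test_closed_form_log_two(self):
        mu = softmax_probabilities(np.array([[math.log(2), 0.0, 0.0]]))
        assert np.allclose(mu, [[0.5, 0.25, 0.25]])

    def test_overflow_safety(self):
        mu = softmax_probabilities(np.array([[800.0, 0.0, 0.0]]))
        assert np.isfinite(mu).all()
        assert mu[0, 0] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, rng):
        data = random_dataset(rng)
        params = random_params(rng)
        mu = class_probabilities(params, data)
        assert np.allclose(mu.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(mu > 0) and np.all(mu < 1)

    def test_nonfinite_predictor_raises(self):
        with pytest.raises(FloatingPointError):
            softmax_probabilities(np.array([[np.nan, 0.0]]))


class TestLogLikelihood:
    def test_zero_params_value(self, rng):
        data = random_dataset(rng, n=6, K=3)
        params = ModelParams.zeros((3, 2, 2), K=3)
        assert log_likelihood(params, data) == pytest.approx(6 * math.log(1 / 3), abs=1e-12)

    def test_matches_naive_loop(self, rng):
        data = random_dataset(rng)
        params = random_params(rng)
        mu = class_probabilities(params, data)
        direct = sum(
            math.log(mu[i, data.label_indices[i]]) for i in range(data.n)
        )
        assert log_likelihood(params, data) == pytest.approx(direct, rel=1e-10)
        assert log_likelihood(params, data) <= 0

    def test_invariant_under_cp_rescaling(self, rng):
        data = random_dataset(rng)
        params = random_params(rng)
        ll = log_likelihood(params, data)
        c = 2.5
        rescaled = params.copy()
        rescaled.cp[0].factors[0] *= c
        rescaled.cp[0].factors[1] /= c
        assert log_likelihood(rescaled, data) == pytest.approx(ll, rel=1e-10)


class TestGradient:
    def test_intercept_gradient_zero_at_balanced_symmetric_start(self, rng):
        # balanced labels, zero parameters: residuals cancel exactly
        X = rng.normal(size=(6, 3, 2, 2))
        y = np.repeat([0, 1, 2], 2)
        data = Dataset.from_arrays(X, y)
        params = ModelParams.zeros((3, 2, 2), K=3, with_intercepts=True)
        grad = log_likelihood_gradient(params, data)
        assert np.allclose(grad.intercepts, 0.0, atol=1e-12)

    @pytest.mark.parametrize("intercepts,p", [(False, 0), (True, 0), (True, 2)])
    def test_matches_central_finite_differences(self, rng, intercepts, p):
        data = random_dataset(rng, n=4, covariates=bool(p))
        params = random_params(rng, intercepts=intercepts, p=p)
        for t in params.cp:
            for j in range(3):
                t.factors[j] *= 0.3
        grad = log_likelihood_gradient(params, data)
        h = 1e-6

        def fd(setter):
            p_plus, p_minus = params.copy(), params.copy()
            setter(p_plus, +h)
            setter(p_minus, -h)
            return (log_likelihood(p_plus, data) - log_likelihood(p_minus, data)) / (2 * h)

        for m in range(2):
            for j in range(3):
                U = params.cp[m].factors[j]
                for idx in np.ndindex(U.shape):
                    def bump(pp, eps, m=m, j=j, idx=idx):
                        pp.cp[m].factors[j][idx] += eps

                    num = fd(bump)
                    ana = grad.cp[m].factors[j][idx]
                    assert ana == pytest.approx(num, rel=1e-5, abs=1e-8)
        if intercepts:
            for m in range(2):
                def bump_a(pp, eps, m=m):
                    pp.intercepts[m] += eps

                assert grad.intercepts[m] == pytest.approx(fd(bump_a), rel=1e-5, abs=1e-8)
        if p:
            for m in range(2):
                for q in range(p):
                    def bump_g(pp, eps, m=m, q=q):
                        pp.covariate_coefs[m, q] += eps

                    assert grad.covariate_coefs[m, q] == pytest.approx(
                        fd(bump_g), rel=1e-5, abs=1e-8
                    )

    def test_reference_class_has_no_parameters(self, rng):
        params = random_params(rng)
        assert len(params.cp) == params.K - 1
        assert params.reference_class not in params.nonreference_classes
        assert params.nonreference_classes == [0, 1]


class TestPredict:
    def test_zero_params_tie_breaks_to_lowest_index(self, rng):
        data = random_dataset(rng)
        params = ModelParams.zeros((3, 2, 2), K=3)
        assert np.array_equal(predict_labels(params, data), np.zeros(6, dtype=int))

    def test_argmax_of_probabilities(self):
        assert np.argmax([0.1, 0.7, 0.2]) == 1  # convention check only via our API:
        mu = np.array([[0.1, 0.7, 0.2]])
        assert mu.argmax(axis=1)[0] == 1


class TestBinaryReduction:
    def test_two_class_case_is_logistic(self, rng):
        """For K=2 the class-0 probability is the logistic function of the
        materialized-tensor inner product."""
        data = random_dataset(rng, K=2)
        params = random_params(rng, K=2)
        mu = class_probabilities(params, data)
        B = params.cp[0].materialize()
        for i in range(data.n):
            eta = float(np.sum(B * data.images[i]))
            assert mu[i, 0] == pytest.approx(expit(eta), rel=1e-10)


class TestParameterCounting:
    def test_full_size_configuration(self):
        assert count_free_parameters((79, 95, 79), K=3, rank=1) == 506

    def test_matches_params_object(self, rng):
        params = random_params(rng, shape=(3, 2, 2), K=3, rank=2)
        assert params.n_free_parameters == 2 * 2 * (3 + 2 + 2)


class TestDatasetValidation:
    def test_rejects_bad_labels(self, rng):
        X = rng.normal(size=(2, 2, 2, 2))
        with pytest.raises(ValueError, match="one-hot"):
            Dataset(X, np.array([[1, 1, 0], [0, 0, 1]]), ["a", "b", "c"])

    def test_rejects_nonfinite_images(self):
        X = np.zeros((2, 2, 2, 2))
        X[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            Dataset.from_arrays(X, [0, 1], class_names=["a", "b"])

    def test_model_requires_n_at_least_K(self, rng):
        data = random_dataset(rng, n=3, K=3).subset([0, 1])
        with pytest.raises(ValueError, match="at least"):
            MultinomialTensorRegression(data)
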
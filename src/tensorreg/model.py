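"""Multinomial tensor regression model.

The model classifies subjects into K classes from a 3-D image covariate
``X_i`` (and optionally a scalar-covariate vector ``Z_i``).  One class is
the *reference*: its linear predictor is fixed at zero.  For each
non-reference class k the predictor is

    eta_ik = alpha_k + <gamma_k, Z_i> + <B_k, X_i>,

where ``B_k`` is a coefficient tensor constrained to a rank-R CP
decomposition (see :mod:`tensorreg.tensor_algebra`), so the image part
contributes only ``R*(d1+d2+d3)`` free parameters per class instead of one
per voxel.  Class probabilities are the softmax of
``(eta_i1, ..., eta_i,K-1, 0)`` and parameters are estimated by maximum
likelihood (:mod:`tensorreg.estimation`).

By default the model has no intercepts and no scalar covariates — the
log-odds of each class against the reference is the pure tensor inner
product ``<B_k, X_i>``; ``use_intercepts=True`` enables the general form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .tensor_algebra import CPTensor, n_voxels

__all__ = [
    "Dataset",
    "ModelParams",
    "MultinomialTensorRegression",
    "linear_predictors",
    "class_probabilities",
    "log_likelihood",
    "log_likelihood_gradient",
    "predict_labels",
    "count_free_parameters",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Aligned collection of 3-D volumes, one-hot labels and covariates.

    Attributes
    ----------
    images : ndarray, shape (n, d1, d2, d3)
    labels : ndarray, shape (n, K)
        One-hot class indicator matrix; each row sums to 1.
    class_names : list of str, length K
    covariates : ndarray (n, p), optional
    """

    images: np.ndarray
    labels: np.ndarray
    class_names: list
    covariates: Optional[np.ndarray] = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.images.ndim != 4:
            raise ValueError(
                f"images must be a (n, d1, d2, d3) array, got ndim={self.images.ndim}"
            )
        if not np.all(np.isfinite(self.images)):
            raise ValueError("images contain non-finite voxels")
        n, K = self.labels.shape
        if n != self.images.shape[0]:
            raise ValueError(
                f"{self.images.shape[0]} images but {n} label rows"
            )
        if n < 1 or K < 2:
            raise ValueError("need n >= 1 subjects and K >= 2 classes")
        if not np.all(np.isin(self.labels, (0, 1))) or not np.all(
            self.labels.sum(axis=1) == 1
        ):
            raise ValueError("labels must be one-hot rows")
        if len(self.class_names) != K:
            raise ValueError(f"{len(self.class_names)} class names for K={K}")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows do not match number of subjects")

    @classmethod
    def from_arrays(
        cls,
        images,
        label_indices,
        class_names: Optional[Sequence[str]] = None,
        covariates=None,
    ) -> "Dataset":
        """Build from integer class indices instead of one-hot rows."""
        y = np.asarray(label_indices, dtype=int)
        K = int(y.max()) + 1 if class_names is None else len(class_names)
        if class_names is None:
            class_names = [f"class_{k}" for k in range(K)]
        onehot = np.zeros((len(y), K), dtype=int)
        onehot[np.arange(len(y)), y] = 1
        return cls(np.asarray(images, dtype=float), onehot, list(class_names), covariates)

    @property
    def n(self) -> int:
        return self.images.shape[0]

    @property
    def K(self) -> int:
        return self.labels.shape[1]

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return self.images.shape[1:]

    @property
    def n_voxels(self) -> int:
        return n_voxels(self.image_shape)

    @property
    def label_indices(self) -> np.ndarray:
        return self.labels.argmax(axis=1)

    @property
    def class_counts(self) -> np.ndarray:
        return self.labels.sum(axis=0)

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        cov = None if self.covariates is None else self.covariates[idx]
        return Dataset(self.images[idx], self.labels[idx], list(self.class_names), cov)


@dataclass
class ModelParams:
    """Full parameter set Theta of the multinomial tensor model.

    ``cp[m]`` is the CP coefficient tensor of the m-th non-reference class
    (classes in original order, skipping ``reference_class``).  The
    reference class carries no parameters.
    """

    cp: list  # K-1 CPTensors
    reference_class: int
    intercepts: Optional[np.ndarray] = None       # (K-1,)
    covariate_coefs: Optional[np.ndarray] = None  # (K-1, p)

    def __post_init__(self):
        shapes = {t.shape for t in self.cp}
        ranks = {t.rank for t in self.cp}
        if len(shapes) != 1 or len(ranks) != 1:
            raise ValueError("all CP tensors must share shape and rank")
        if self.intercepts is not None:
            self.intercepts = np.asarray(self.intercepts, dtype=float)
            if self.intercepts.shape != (len(self.cp),):
                raise ValueError("need one intercept per non-reference class")
        if self.covariate_coefs is not None:
            self.covariate_coefs = np.atleast_2d(
                np.asarray(self.covariate_coefs, dtype=float)
            )
            if self.covariate_coefs.shape[0] != len(self.cp):
                raise ValueError("need one covariate row per non-reference class")

    @classmethod
    def zeros(
        cls,
        shape,
        K: int,
        rank: int = 1,
        reference_class: Optional[int] = None,
        with_intercepts: bool = False,
        n_covariates: int = 0,
    ) -> "ModelParams":
        ref = K - 1 if reference_class is None else reference_class
        return cls(
            cp=[CPTensor.zeros(shape, rank) for _ in range(K - 1)],
            reference_class=ref,
            intercepts=np.zeros(K - 1) if with_intercepts else None,
            covariate_coefs=np.zeros((K - 1, n_covariates)) if n_covariates else None,
        )

    @property
    def K(self) -> int:
        return len(self.cp) + 1

    @property
    def rank(self) -> int:
        return self.cp[0].rank

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cp[0].shape

    @property
    def nonreference_classes(self) -> list:
        """Original class indices carrying parameters, in order."""
        return [k for k in range(self.K) if k != self.reference_class]

    def copy(self) -> "ModelParams":
        return ModelParams(
            cp=[t.copy() for t in self.cp],
            reference_class=self.reference_class,
            intercepts=None if self.intercepts is None else self.intercepts.copy(),
            covariate_coefs=None
            if self.covariate_coefs is None
            else self.covariate_coefs.copy(),
        )

    @property
    def n_free_parameters(self) -> int:
        n = sum(t.n_free_parameters for t in self.cp)
        if self.intercepts is not None:
            n += self.intercepts.size
        if self.covariate_coefs is not None:
            n += self.covariate_coefs.size
        return n


def count_free_parameters(
    shape, K: int, rank: int = 1, with_intercepts: bool = False, n_covariates: int = 0
) -> int:
    """(K-1)*R*(d1+d2+d3) plus intercept/covariate parameters if enabled."""
    n = (K - 1) * rank * sum(int(d) for d in shape)
    if with_intercepts:
        n += K - 1
    n += (K - 1) * n_covariates
    return n


# ---------------------------------------------------------------------------
# model mathematics
# ---------------------------------------------------------------------------

def linear_predictors(params: ModelParams, images, covariates=None) -> np.ndarray:
    """Full (n, K) predictor matrix; the reference column is identically 0."""
    X = np.asarray(images, dtype=float)
    single = X.ndim == 3
    if single:
        X = X[None]
    if X.shape[1:] != params.shape:
        raise ValueError(
            f"image shape {X.shape[1:]} does not match coefficient shape {params.shape}"
        )
    n = X.shape[0]
    eta = np.zeros((n, params.K))
    for m, k in enumerate(params.nonreference_classes):
        U1, U2, U3 = params.cp[m].factors
        eta[:, k] = np.einsum("nabc,ar,br,cr->n", X, U1, U2, U3, optimize=True)
        if params.intercepts is not None:
            eta[:, k] += params.intercepts[m]
        if params.covariate_coefs is not None:
            if covariates is None:
                raise ValueError("params include covariate coefficients but no covariates given")
            Z = np.atleast_2d(np.asarray(covariates, dtype=float))
            eta[:, k] += Z @ params.covariate_coefs[m]
    return eta[0] if single else eta


def class_probabilities(params: ModelParams, data: Dataset) -> np.ndarray:
    """Softmax class-probability matrix mu (n, K); rows sum to 1."""
    eta = linear_predictors(params, data.images, data.covariates)
    return softmax_probabilities(eta)


def softmax_probabilities(eta: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety."""
    eta = np.atleast_2d(eta)
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor; fit diverged?")
    shifted = eta - eta.max(axis=1, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=1, keepdims=True)


def log_likelihood(params: ModelParams, data: Dataset) -> float:
    """Multinomial log-likelihood ``sum_i sum_k y_ik log mu_ik`` (always <= 0)."""
    eta = linear_predictors(params, data.images, data.covariates)
    return _loglik_from_eta(eta, data.label_indices)


def _loglik_from_eta(eta: np.ndarray, y_idx: np.ndarray) -> float:
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor; fit diverged?")
    return float(
        np.sum(eta[np.arange(len(y_idx)), y_idx]) - np.sum(logsumexp(eta, axis=1))
    )


def log_likelihood_gradient(params: ModelParams, data: Dataset) -> ModelParams:
    """Analytic gradient of the log-likelihood, congruent to ``params``.

    Uses the chain rule through the CP structure: with softmax residual
    ``r_ik = y_ik - mu_ik``, the gradient w.r.t. the mode-j factor of class
    k is the residual-weighted sum of the images contracted against the
    other two factors of the same tensor.
    """
    X = data.images
    mu = class_probabilities(params, data)
    resid = data.labels - mu  # (n, K)
    grad_cp = []
    for m, k in enumerate(params.nonreference_classes):
        U1, U2, U3 = params.cp[m].factors
        r = resid[:, k]
        g1 = np.einsum("n,nabc,br,cr->ar", r, X, U2, U3, optimize=True)
        g2 = np.einsum("n,nabc,ar,cr->br", r, X, U1, U3, optimize=True)
        g3 = np.einsum("n,nabc,ar,br->cr", r, X, U1, U2, optimize=True)
        grad_cp.append(CPTensor([g1, g2, g3]))
    nonref = params.nonreference_classes
    g_alpha = resid[:, nonref].sum(axis=0) if params.intercepts is not None else None
    g_gamma = (
        resid[:, nonref].T @ data.covariates
        if params.covariate_coefs is not None
        else None
    )
    return ModelParams(
        cp=grad_cp,
        reference_class=params.reference_class,
        intercepts=g_alpha,
        covariate_coefs=g_gamma,
    )


def predict_labels(params: ModelParams, data: Dataset) -> np.ndarray:
    """Per-subject argmax class index (ties broken toward the lowest index)."""
    mu = class_probabilities(params, data)
    return mu.argmax(axis=1)


# ---------------------------------------------------------------------------
# the Model object
# ---------------------------------------------------------------------------

class MultinomialTensorRegression:
    """K-class softmax regression with CP-structured image coefficients.

    Parameters
    ----------
    data : Dataset
        Training volumes, one-hot labels, optional covariates.
    rank : int
        CP rank R of each class's coefficient tensor (default 1).
    reference_class : int, optional
        Index of the baseline class whose predictor is fixed at 0;
        defaults to the last class.
    use_intercepts : bool
        Enable per-class intercepts (and covariate coefficients when the
        dataset carries covariates).  Off by default: the canonical model
        is the pure tensor form.
    standardize : bool
        Globally z-score voxel intensities by the training mean/sd; the
        statistics are stored on the model so held-out volumes reuse them.

    Examples
    --------
    >>> from tensorreg.synthetic import SyntheticScenario, generate
    >>> data, truth = generate(SyntheticScenario(seed=7))
    >>> model = MultinomialTensorRegression(data)
    >>> res = model.fit(seed=0)
    >>> res.converged
    True
    """

    def __init__(
        self,
        data: Dataset,
        rank: int = 1,
        reference_class: Optional[int] = None,
        use_intercepts: bool = False,
        standardize: bool = False,
    ):
        if data.n < data.K:
            raise ValueError(f"need at least K={data.K} subjects, got n={data.n}")
        self.data = data
        self.rank = int(rank)
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        self.reference_class = (
            data.K - 1 if reference_class is None else int(reference_class)
        )
        if not 0 <= self.reference_class < data.K:
            raise ValueError(
                f"reference_class {reference_class} outside 0..{data.K - 1}"
            )
        self.use_intercepts = bool(use_intercepts)
        self.standardize = bool(standardize)
        if self.standardize:
            self.voxel_mean = float(data.images.mean())
            self.voxel_sd = float(data.images.std())
            if self.voxel_sd == 0:
                raise ValueError("cannot standardize constant images")
        else:
            self.voxel_mean, self.voxel_sd = 0.0, 1.0

    # -- data access -------------------------------------------------------

    def transform_images(self, images) -> np.ndarray:
        """Apply the training-set standardization (identity if disabled)."""
        X = np.asarray(images, dtype=float)
        if self.standardize:
            X = (X - self.voxel_mean) / self.voxel_sd
        return X

    def _training_view(self) -> Dataset:
        if not self.standardize:
            return self.data
        return Dataset(
            self.transform_images(self.data.images),
            self.data.labels,
            list(self.data.class_names),
            self.data.covariates,
        )

    @property
    def n_covariates(self) -> int:
        return 0 if self.data.covariates is None else self.data.covariates.shape[1]

    @property
    def n_free_parameters(self) -> int:
        return count_free_parameters(
            self.data.image_shape,
            self.data.K,
            self.rank,
            self.use_intercepts,
            self.n_covariates if self.use_intercepts else 0,
        )

    def initial_params(self, init_scale: float, rng: np.random.Generator) -> ModelParams:
        shape, K = self.data.image_shape, self.data.K
        cp = [
            CPTensor([init_scale * rng.standard_normal((d, self.rank)) for d in shape])
            for _ in range(K - 1)
        ]
        return ModelParams(
            cp=cp,
            reference_class=self.reference_class,
            intercepts=np.zeros(K - 1) if self.use_intercepts else None,
            covariate_coefs=(
                np.zeros((K - 1, self.n_covariates))
                if self.use_intercepts and self.n_covariates
                else None
            ),
        )

    # -- likelihood interface ---------------------------------------------

    def loglike(self, params: ModelParams) -> float:
        return log_likelihood(params, self._training_view())

    def score(self, params: ModelParams) -> ModelParams:
        """Gradient of the log-likelihood at ``params`` (same structure)."""
        return log_likelihood_gradient(params, self._training_view())

    def predict(self, params: ModelParams, data: Optional[Dataset] = None) -> np.ndarray:
        data = self.data if data is None else data
        view = Dataset(
            self.transform_images(data.images),
            data.labels,
            list(data.class_names),
            data.covariates,
        )
        return predict_labels(params, view)

    def predict_proba(self, params: ModelParams, data: Optional[Dataset] = None) -> np.ndarray:
        data = self.data if data is None else data
        view = Dataset(
            self.transform_images(data.images),
            data.labels,
            list(data.class_names),
            data.covariates,
        )
        return class_probabilities(params, view)

    def fit(self, config=None, **kwargs):
        """Maximum-likelihood fit by block relaxation (see
        :func:`tensorreg.estimation.fit_model`).  Keyword arguments override
        :class:`~tensorreg.estimation.FitConfig` fields.

        Returns
        -------
        TensorRegressionResults
        """
        from .estimation import FitConfig, fit_model

        if config is None:
            config = FitConfig(**kwargs)
        elif kwargs:
            config = config.replace(**kwargs)
        return fit_model(self, config)
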
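"""Synthetic volumes with planted low-rank class signals.

The generator produces datasets with exactly the statistical structure the
multinomial tensor model assumes, so ground-truth parameters are known and
parameter recovery can be measured.  Each non-reference class k owns a
rank-1 "bump" tensor ``T_k = b_k^1 o b_k^2 o b_k^3`` whose mode profiles
are smooth half-sine windows over a contiguous index range (a localized
"region"), peak-normalized to 1.  Windows of different classes sit at
different positions so the regions are disjoint.

Two label mechanisms:

``planted``
    Labels are assigned first (exact per-class counts).  A subject of
    class c receives the signed mean signal
    ``sum_k s_k(c) * (amplitude/2) * T_k`` with ``s_k(c) = +1`` if
    ``c == k`` else ``-1``, plus i.i.d. Gaussian voxel noise.  The +/-
    coding makes the class means symmetric, so the exact Bayes posterior
    is an intercept-free multinomial tensor model with
    ``B_k = (amplitude / noise_sd^2) * T_k`` — these are the ground-truth
    parameters returned.  The peak voxel contrast between class k and any
    other class is ``amplitude``, hence ``amplitude / noise_sd`` is the
    planted signal-to-noise ratio (default 6).

``model``
    Volumes are pure noise and labels are drawn from the multinomial
    probabilities at the same ground-truth parameters, i.e. directly from
    the model's own generative process.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .model import Dataset, ModelParams, class_probabilities
from .tensor_algebra import CPTensor

__all__ = [
    "SyntheticScenario",
    "make_true_params",
    "generate",
    "stratified_split",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic dataset.

    ``n_per_class`` may be a single int (balanced) or one count per class.
    ``amplitude`` is the peak voxel contrast of each planted class signal;
    with ``noise_sd=1`` it equals the signal-to-noise ratio.
    ``window_fraction`` sets the side length of each class's active window
    as a fraction of the corresponding image dimension.
    """

    shape: tuple = (20, 24, 20)
    n_per_class: Union[int, tuple] = 100
    K: int = 3
    rank: int = 1
    amplitude: float = 6.0
    noise_sd: float = 1.0
    window_fraction: float = 0.25
    mechanism: str = "planted"
    reference_class: Optional[int] = None  # default: last class
    seed: int = 7

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.mechanism not in ("planted", "model"):
            raise ValueError(f"mechanism must be 'planted' or 'model', got {self.mechanism!r}")
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")
        if isinstance(self.n_per_class, (tuple, list)):
            if len(self.n_per_class) != self.K:
                raise ValueError("n_per_class tuple must have one entry per class")
            if any(c < 1 for c in self.n_per_class):
                raise ValueError("every class needs at least one subject")
        elif self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")

    @property
    def class_counts(self) -> np.ndarray:
        if isinstance(self.n_per_class, (tuple, list)):
            return np.asarray(self.n_per_class, dtype=int)
        return np.full(self.K, int(self.n_per_class), dtype=int)

    @property
    def class_names(self) -> list:
        return [f"class_{k}" for k in range(self.K)]


def _bump_profile(length: int, center_frac: float, window_fraction: float) -> np.ndarray:
    """Half-sine window of width ~window_fraction*length centred at
    center_frac*length, peak-normalized to 1; zero elsewhere."""
    width = max(3, int(round(window_fraction * length)))
    center = int(round(center_frac * length))
    start = int(np.clip(center - width // 2, 0, length - width))
    prof = np.zeros(length)
    i = np.arange(width)
    win = np.sin(np.pi * (i + 1) / (width + 1))
    prof[start : start + width] = win / win.max()
    return prof


def _bump_tensors(scenario: SyntheticScenario) -> list:
    """One rank-``rank`` bump CPTensor per non-reference class.

    For rank > 1, additional rank-1 terms are placed in extra windows with
    geometrically decaying weight so the leading term dominates.
    """
    K = scenario.K
    ref = K - 1 if scenario.reference_class is None else scenario.reference_class
    nonref = [k for k in range(K) if k != ref]
    n_slots = len(nonref) * scenario.rank
    centers = np.linspace(0.25, 0.75, n_slots) if n_slots > 1 else np.array([0.5])
    tensors = []
    slot = 0
    for _ in nonref:
        terms = []
        for r in range(scenario.rank):
            weight = 0.5**r
            vecs = [
                _bump_profile(d, centers[slot], scenario.window_fraction)
                for d in scenario.shape
            ]
            vecs[0] = vecs[0] * weight
            terms.append(vecs)
            slot += 1
        tensors.append(CPTensor.from_vectors(*terms))
    return tensors


def make_true_params(scenario: SyntheticScenario) -> ModelParams:
    """Ground-truth parameters: ``B_k = (amplitude / noise_sd^2) * T_k``."""
    K = scenario.K
    ref = K - 1 if scenario.reference_class is None else scenario.reference_class
    scale = scenario.amplitude / scenario.noise_sd**2
    return ModelParams(
        cp=[scale * T for T in _bump_tensors(scenario)],
        reference_class=ref,
    )


def generate(scenario: SyntheticScenario) -> tuple[Dataset, ModelParams]:
    """Draw one dataset; returns ``(dataset, true_params)``."""
    rng = np.random.default_rng(scenario.seed)
    counts = scenario.class_counts
    n = int(counts.sum())
    K = scenario.K
    ref = K - 1 if scenario.reference_class is None else scenario.reference_class
    nonref = [k for k in range(K) if k != ref]
    bumps = [T.materialize() for T in _bump_tensors(scenario)]
    true_params = make_true_params(scenario)

    noise = scenario.noise_sd * rng.standard_normal((n,) + tuple(scenario.shape))

    if scenario.mechanism == "planted":
        y = np.repeat(np.arange(K), counts)
        images = noise
        half = scenario.amplitude / 2.0
        for m, k in enumerate(nonref):
            sign = np.where(y == k, 1.0, -1.0)
            images += sign[:, None, None, None] * (half * bumps[m])[None]
        perm = rng.permutation(n)
        images, y = images[perm], y[perm]
    else:  # "model": labels drawn from the multinomial at the true params
        images = noise
        tmp = Dataset.from_arrays(
            images, np.zeros(n, dtype=int), class_names=scenario.class_names
        )
        mu = class_probabilities(true_params, tmp)
        u = rng.random(n)
        y = (mu.cumsum(axis=1) < u[:, None]).sum(axis=1)

    data = Dataset.from_arrays(images, y, class_names=scenario.class_names)
    return data, true_params


def stratified_split(
    data: Dataset, test_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Random train/test partition retaining the class ratio.

    Per-class test counts follow the largest-remainder rule: floors of
    ``count * test_fraction``, then one extra subject per class in order of
    decreasing fractional remainder until the total equals
    ``round(test_fraction * n)``.  Deterministic given ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    y = data.label_indices
    counts = data.class_counts
    if int(counts.min()) < 2:
        raise ValueError("every class needs at least 2 members to split")
    rng = np.random.default_rng(seed)

    exact = counts * test_fraction
    base = np.floor(exact).astype(int)
    total = int(round(test_fraction * data.n))
    remainder = exact - base
    short = total - int(base.sum())
    order = np.argsort(-remainder, kind="stable")
    for k in order[:max(short, 0)]:
        base[k] += 1

    test_idx = []
    for k in range(data.K):
        members = np.flatnonzero(y == k)
        chosen = rng.permutation(members)[: base[k]]
        test_idx.append(chosen)
    test_idx = np.sort(np.concatenate(test_idx))
    mask = np.zeros(data.n, dtype=bool)
    mask[test_idx] = True
    return data.subset(np.flatnonzero(~mask)), data.subset(test_idx)
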
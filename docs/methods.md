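# Methods

## Model

`tensorreg` fits a K-class multinomial logistic (softmax) regression in
which the coefficient array attached to a 3-way image covariate is
constrained to a rank-R CP decomposition.  For subject i with volume
`X_i ∈ R^{d1×d2×d3}`, optional scalar covariates `Z_i` and one-hot label
`Y_i`:

- linear predictor of non-reference class k:
  `η_ik = α_k + ⟨γ_k, Z_i⟩ + ⟨B_k, X_i⟩`, with `B_k = Σ_r β_{k,r}^1 ∘
  β_{k,r}^2 ∘ β_{k,r}^3`; the reference class has `η = 0` and carries no
  parameters.
- class probabilities: softmax of `(η_i1, …, η_i,K−1, 0)`.
- log-likelihood: `l(Θ) = Σ_i Σ_k y_ik log μ_ik`.

The CP constraint reduces the image-coefficient dimension from
`Π_j d_j` to `R·Σ_j d_j` per class.  The rank-1 default matches the
regime the method targets (clinical n of a few hundred); the code supports
any `R ≥ 1`.  The default likelihood has no intercepts or covariates; both
are available via `use_intercepts=True`.  Intercept-free fitting assumes
the predictors carry class information through the inner product with the
volumes themselves — appropriate for intensity images whose class-mean
differences are not centered away.

The model makes the usual multinomial-logit assumptions: independent
subjects, correctly aligned (spatially normalized) volumes of one common
shape, and class log-odds linear in the image.  CP scale/sign
indeterminacy (rescaling `β^1` by c and `β^2` by 1/c, or flipping the sign
of two factors) leaves `B_k` and hence the likelihood unchanged; all
comparisons of fitted coefficients therefore use scale/sign-invariant
statistics (cosine similarity of materialized tensors).

## Estimation

Maximum likelihood by **block relaxation**: blocks are the factor vectors
`β_k^j` for j = 1,2,3 and k = 1..K−1 (plus one intercept/covariate block
when enabled), visited in that order within an outer sweep.  Each visit
runs `inner_steps` Adam iterations on the negative log-likelihood with all
other blocks held fixed.  The sweep-level stopping rule is
`|l(Θ(t+1)) − l(Θ(t))| < ε`.  Since the per-block objective has no closed
argmax for K > 2, the fixed Adam budget per visit *is* the definition of
the block update here; the best-seen parameters are returned.

Per-block cost is kept low by precomputing, once per visit, the
contraction of every volume against the two fixed factors of the active
tensor (an `(n, d_j, R)` array); each Adam step then costs `O(n d_j R)`.
The identity behind this is the Khatri–Rao/matricization form
`⟨B, X⟩ = β^j · X_(j) · (β^{j'} ⊗ β^{j''})` for the *same* tensor's other
two modes, with the unfolding convention fixed in one place
(`tensor_algebra.mode_unfold`: mode j to the front, remaining modes in
increasing order, C-order reshape).

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `rank` | 1 | CP rank R of every class tensor |
| `epsilon` | 1e-4 | outer-loop tolerance on the log-likelihood change (likelihood units) |
| `max_outer_iters` | 200 | sweep cap |
| `inner_steps` | 25 | Adam iterations per block visit |
| `learning_rate` | 0.01 | Adam step size (tunable by stratified K-fold CV) |
| `adam_beta1/2` | 0.9 / 0.999 | Adam moment decays |
| `adam_eps_scale` | 10 | damping constant multiplier (below) |
| `init_scale` | 0.01 | sd of the i.i.d. normal factor initialization |
| `mode` | "block" | "joint" runs one Adam pass over all parameters as a cross-check |

**Adam damping.** Each block visit sets Adam's denominator constant to
`max(adam_eps, adam_eps_scale × RMS(g0))`, where `g0` is the visit's first
gradient.  With the conventional tiny constant (1e-8) alone, Adam's
per-coordinate normalization moves every coordinate whose within-visit
gradient sign is constant by the same ±lr step.  When the classes are
separable the likelihood saturates after a few sweeps and this sign-like
update freezes the factors into a flat ± profile: the *shape* of the
coefficient vector (which voxels matter more) is lost even though
classification is perfect.  Damping at the scale of the gradient keeps
steps proportional to gradient magnitude — the update interpolates toward
plain first-order ascent with momentum — and preserves the coefficient
profile, which is the point of the model.  `adam_eps_scale=0` restores
textbook Adam.

**Learning-rate selection.** `tune_learning_rate` scores each grid value
by mean held-out prediction accuracy over stratified K-fold CV (default
10-fold), ties toward the smaller rate, deterministic given the seed.
Held-out accuracy is the selection criterion; MAUC can be computed from
the same fits if preferred.

**Numerical safety.** Probabilities use max-subtracted softmax; the
log-likelihood is computed directly from predictors via log-sum-exp, so no
log of a zero probability is ever taken.  A non-finite predictor or
likelihood aborts the fit with an error naming the block and iteration.
With all predictors zero the log-likelihood is exactly `n·log(1/K)`.

**Monotonicity.** Block relaxation with exact block solves is an ascent
method.  With fixed Adam budgets the trace can in principle dip by a small
solver tolerance; the tests assert no decrease exceeds 1e-3 likelihood
units, and in practice every sweep improves at the default settings.

**Reproducibility.** All randomness (initialization, data generation, CV
folds, splits) flows through explicit seeds; the same seed and
configuration reproduce a fit bit-for-bit on one platform.

## Synthetic data

The generator emulates the data-generating process the model assumes, at
desk scale.  Default scenario: volumes `20×24×20` (unequal dims preserve
the 3-way bookkeeping of full-size data at ~1.6% of the voxels), three
classes, 100 subjects per class, i.i.d. unit-normal voxel noise.  Each
non-reference class owns a rank-1 bump tensor `T_k` — per mode, a half-sine
profile over a contiguous window of ~25% of the dimension, peak-normalized
to 1, windows disjoint across classes — mimicking a localized structural
alteration.

**Planted mechanism (default).**  Labels are assigned first (exact
per-class counts); a subject of class c receives mean signal
`Σ_k s_k(c)·(amplitude/2)·T_k`, with `s_k(c) = +1` when `c = k` and −1
otherwise.  The symmetric ± coding is deliberate: the class means are then
equidistant from the origin, so the exact Bayes posterior is itself an
intercept-free multinomial tensor model with
`B_k = (amplitude/noise_sd²)·T_k`.  This makes the planted data
model-consistent (the returned ground truth is the true minimizer of the
population risk), trainable to perfect accuracy without intercepts, and
the natural target for recovery diagnostics.  A one-sided planting (signal
only in class k's volumes, reference pure noise) would require intercepts
for separation, because any linear score of zero-mean noise is
sign-symmetric.  The default amplitude 6 (peak voxel contrast between a
class and the rest, in noise-sd units) puts the scenario in the strongly
separated regime the training-set benchmark calls for.

**Model mechanism.**  Volumes are pure noise and labels are drawn from the
multinomial probabilities at the ground-truth parameters — the model's own
generative process, used for calibration checks (empirical class
frequencies match the mean of the true probability matrix).

What the generator does *not* emulate: anatomical texture, intensity
nonstationarity, registration error, inter-scanner variation and spatial
noise correlation.  Passing tests therefore demonstrate correctness of the
estimator and metrics under the model's own assumptions — not clinical
performance; headline numbers on real cohorts are not reproducible from
synthetic data.

**Stratified splitting** keeps per-class test counts within one subject of
`count × test_fraction` by the largest-remainder rule (floors, then +1 in
order of decreasing fractional remainder until the total matches
`round(fraction × n)`); e.g. an 84:192:200 cohort at 20% yields 17/38/40.

## Problem sizes

The test suite and the reproduction script run the default scenario
(300 subjects of 20×24×20, a fit in well under a minute) and smaller
instances for unit checks: gradient correctness at 3×2×2 with n = 4
against central finite differences (relative error < 1e-5, step 1e-6);
the two-class reduction against an unpenalized vectorized logistic
regression at 3×4×3 with n = 2000 (coefficient correlation > 0.8 — the
rank-1 constraint and finite n keep it below 1); null-model behavior at
3×4×3 with n = 500, where parameters are few enough relative to n that
the intercept-enabled fit cannot separate noise and held-out accuracy
settles at the majority-class rate.  A full-size 79×95×79 generation
smoke test verifies shape handling and the 592,895-voxel count.

## Design choices and limitations

- Reference class defaults to the last class and is configurable; with
  K = 2 the model is exactly binary logistic tensor regression.
- The plain (unadjusted) Rand index is reported; an adjusted variant is
  available but not part of the headline metrics.
- Pairwise AUCs use midrank (half-credit) tie handling; MAUC is the
  Hand–Till average of `[Â(i|j) + Â(j|i)]/2` over unordered pairs, each
  direction scored by that class's own probability column.
- Voxel intensities are consumed as given by default; optional global
  z-scoring by training-set statistics is stored with the fit and reused
  at prediction time.
- No penalization or shrinkage priors: on separable data the MLE direction
  is finite-iteration-optimizer-dependent, which is why recovery is
  assessed with scale/sign-invariant cosines and why `epsilon` stops the
  fit once the likelihood plateaus.
- Dense tensors only, 3-way only; CP *decomposition* of a given full
  tensor is out of scope (CP forms are only ever constructed).
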
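# tensorreg

Multinomial tensor regression for classifying subjects from whole 3-D image
volumes — e.g. distinguishing Parkinson's disease with depression (DPD),
non-depressed Parkinson's disease (NDPD) and healthy controls from spatially
normalized structural MRI — while localizing the image regions that drive
each classification.

## The model

A spatially normalized volume is a 3-way array `X_i ∈ R^{d1×d2×d3}` (for the
motivating sMRI application, 79×95×79 ≈ 593k voxels).  Treating every voxel
as a regression covariate is hopeless at clinical sample sizes, so the
coefficient array of each class is constrained to a rank-R CP
(CANDECOMP/PARAFAC) decomposition:

```
Y_i  ~  Multinomial(μ_i1, …, μ_iK)
log( μ_ik / μ_iK )  =  α_k + ⟨γ_k, Z_i⟩ + ⟨B_k, X_i⟩ ,   k = 1, …, K−1
B_k  =  Σ_{r=1..R}  β_{k,r}^1 ∘ β_{k,r}^2 ∘ β_{k,r}^3
```

with class K the reference, `∘` the vector outer product and `⟨·,·⟩` the
tensor inner product.  One class then costs `R·(d1+d2+d3)` image parameters
instead of `d1·d2·d3` — for K=3, R=1 at 79×95×79 that is 2×(79+95+79) = 506
parameters in place of 592,895 per class.  The default model has no
intercepts or scalar covariates (`α_k = 0`, no `Z_i`); `use_intercepts=True`
enables the general form.

Parameters are estimated by maximum likelihood with **block relaxation**:
the optimizer cycles over the factor vectors `β_k^j` (one block per mode and
class), improving each block by a fixed number of Adam steps while the
others are held fixed, until the log-likelihood change per sweep falls below
a tolerance ε.  Each block subproblem is linear in the active factor through
the mode-j matricization and the Khatri–Rao product of the other two
factors.  Because the `β_k^1 ∘ β_k^2` (and the other two pairwise)
outer-product matrices are low-rank images themselves, the fitted
coefficients can be drawn as heatmaps that mark discriminative regions.

Evaluation uses Prediction Accuracy (PA), the plain Rand index (RI) and the
Hand–Till multi-class AUC (MAUC: the average over class pairs of
symmetrized pairwise AUCs, which reduces to ordinary AUC for K = 2).

## Worked example

Real clinical volumes are restricted, so the package ships a generator that
plants rank-1 class signals (smooth localized bumps) in noise, with known
ground-truth coefficients:

```python
from tensorreg import MultinomialTensorRegression
from tensorreg.synthetic import SyntheticScenario, generate, stratified_split

scenario = SyntheticScenario(seed=7)           # 20x24x20, 100/class, SNR 6
data, truth = generate(scenario)
train, test = stratified_split(data, 0.2, seed=7)

model = MultinomialTensorRegression(train)
res = model.fit(seed=11)
print(res.summary())
print(res.evaluate(test).to_frame().to_string(index=False))
print(res.recovery_report(truth).to_frame().to_string(index=False))
```

prints

```
Multinomial Tensor Regression Results
=============================================
No. observations:      240
No. classes:           3 (class_0, class_1, class_2)
Image shape:           (20, 24, 20)  (9600 voxels)
CP rank:               1
Reference class:       class_2
Free parameters:       128
Log-likelihood:        -0.0000
Converged:             True (18 outer iterations, eps=0.0001)
Optimizer:             block relaxation, Adam lr=0.01, 25 steps/block
---------------------------------------------
Training PA:           1.0000
Training Rand index:   1.0000
Training MAUC:         1.0000

  metric  value
      PA    1.0
      RI    1.0
    MAUC    1.0
AUC(0,1)    1.0
AUC(0,2)    1.0
AUC(1,2)    1.0

 class   cosine  abs_cosine  surface_corr
     0 0.995252    0.995252      0.997099
     1 0.892468    0.892468     -0.932036
```

The fit separates the training classes perfectly (PA = RI = MAUC = 1, the
expected outcome for strongly separated planted signals), generalizes to the
held-out 20% (PA/RI/MAUC 1.0 here), and the materialized fitted tensors
align with the planted ground truth up to the CP scale/sign indeterminacy
(cosine ≈ 0.99 and 0.89; the negative surface correlation is the same fit
with the sign carried by the third mode).  `res.coefficient_surfaces()` or
the `export-surfaces` command render the heatmaps.

The same workflow is available from the shell:

```
tensorreg simulate --out sim --seed 7
tensorreg fit --labels sim/labels.tsv --out params.json --seed 11
tensorreg evaluate --labels sim/labels.tsv --params params.json --report report.tsv
tensorreg export-surfaces --params params.json --out surfaces
tensorreg tune --labels sim/labels.tsv --grid 0.003,0.01,0.03 --folds 10
```

To fit your own data, point `tensorreg fit --labels` at a tab-separated
table with `filename` and `class` columns next to equally-shaped NIfTI
volumes (already spatially normalized), or build a
`tensorreg.Dataset` from arrays in Python.

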
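# Methods

## The prediction problem

Azobenzene-derived photoswitches interconvert between *E* and *Z* isomers
under light. Their usefulness hinges on the positions of the principal
electronic absorption bands: the π–π* and n–π* wavelength maxima (nm) of
each isomer. `azogp` predicts these four quantities from a SMILES string,
treating them as four correlated regression tasks over a shared molecular
representation, and operationalises the predictions in two ways: a sparse
linear correction of physics-based (TD-DFT) wavelength estimates, and a
criterion-based screen of purchasable-compound libraries.

The data regime is small: a few hundred molecules, with most molecules
labelled for only a subset of the four bands (the *E* π–π* band is almost
always reported; the *Z*-isomer bands only for a quarter to a third of
molecules). Exact Gaussian-process inference is therefore both feasible and
attractive — no architecture tuning, calibrated uncertainty, and a
principled way to share statistical strength across tasks.

## Representation: fragprints

Molecules are encoded as non-negative count vectors formed by
concatenating

- a binary Morgan (ECFP-style) circular fingerprint, radius 3, 2048 bits,
  computed with RDKit; and
- occurrence counts of 86 functional-group substructures (azo and azoxy
  linkages, nitro, halogens, amine classes, ethers, heteroaryl rings, …)
  defined by an in-repo SMARTS catalogue.

The catalogue is frozen and versioned inside the package rather than
delegated to a toolkit descriptor set, so feature vectors cannot drift with
toolkit releases. Radius and bit length are conventions, not canon, and are
exposed in `FeatureConfig`. Molecules that fail RDKit sanitisation are
rejected, never repaired; all-zero feature vectors (possible only for
exotic inputs) are logged, and the kernel itself refuses the undefined
0/0 similarity.

## Model

### Tanimoto-kernel GP

For count vectors x, x′ the covariance is the Tanimoto kernel

    k(x, x′) = σ_f² · ⟨x, x′⟩ / (‖x‖² + ‖x′‖² − ⟨x, x′⟩),

a positive-semidefinite kernel on non-negative vectors, with signal
variance σ_f². Targets are z-scored so the prior mean is zero; observation
noise is homoscedastic Gaussian with variance σ_y², which deliberately
absorbs solvent effects (solvent is not part of the representation, and
solvent duplicates are reduced to one record chosen uniformly at random
under a fixed seed). Predictions use the standard exact-GP conditional
mean K(X*,X)[K+σ_y²I]⁻¹y and covariance
K(X*,X*) − K(X*,X)[K+σ_y²I]⁻¹K(X,X*), de-standardised to nm. Reported
variance is latent; `include_noise=True` adds σ_y².

### Multioutput extension (ICM)

The four tasks share the molecular kernel through the intrinsic model of
coregionalisation: cov[(x, task i), (x′, task j)] = k(x, x′)·B[i, j], with
B = LLᵀ positive semidefinite by construction (L lower-triangular, 4×4,
full rank by default, rank configurable). Observations are stacked
(molecule, task, value) triples; a molecule missing a task's label simply
contributes no row. Targets are z-scored per task using that task's
observed labels; a task with zero label variance is an error.

Identifiability: σ_f² multiplies every entry of B, so only the product
σ_f²·B is determined by the likelihood. The MOGP therefore fixes σ_f² = 1
and lets B carry the scale (a `learn_sigma_f2` flag restores the redundant
joint parametrisation). Recovery diagnostics compare the effective
amplitude σ_f²·B against ground truth.

### Fitting

Hyperparameters maximise the log marginal likelihood with analytic
gradients (the standard ½·tr[(ααᵀ − K⁻¹)∂K/∂θ] identity; for L the
per-entry gradients reduce to (C + Cᵀ)L where C aggregates the weighted
kernel over task pairs). Optimisation is multi-restart L-BFGS-B on
log σ_f², log σ_y² and the free entries of L (diagonal through a log
transform), 5 restarts by default from a fixed-seed perturbation of
(σ_f² = 1, σ_y² = 0.1, L = I), tolerance 1e-6. The best likelihood wins;
near-ties (relative 1e-9) break toward the smaller noise variance. Cholesky
factorisations add a jitter of 1e-6 × mean diagonal, escalating tenfold to
1e-2 before raising a numerical error with diagnostics.

A shared homoscedastic σ_y² on the per-task standardised scale is the
default; because task standard deviations differ, this corresponds to
mildly task-dependent noise in nm. A `per_task_noise` flag fits separate
noise variances.

## Evaluation harness

- `metric_suite` reports MAE, mean signed error (prediction − truth,
  diagnosing systematic bias), RMSE, and the standard error of the
  absolute errors (the "standard error" attached to an MAE is defined as
  std(|e|)/√n, since no formula is canonical).
- `random_split_benchmark` runs 20 random 80/20 splits by default; split
  k under seed s is generated by a counter-based RNG key (s, k), so every
  model sees identical folds (paired comparisons) and runs are extensible.
- `loo_benchmark` performs leave-one-out validation with an optional extra
  training pool; any pool entry sharing the held-out molecule's identifier
  is removed for that fold (leakage guard).
- `confidence_error_curve` sorts by ascending predictive variance and
  reports MAE over the retained top fraction, grid {0.05, …, 1.00},
  retained count = ceil(fraction·n), stable ties.
- `wilcoxon_paired` is a two-sided signed-rank test: exact null for
  n ≤ 25 without ties, normal approximation with continuity correction
  otherwise; zero differences discarded (classic policy; Pratt behind a
  flag).

## Residual correction of TD-DFT predictions

TD-DFT wavelengths show systematic deviation (a nearly constant shift for
a given functional). The correction models the residual
r = experimental − computed with a Lasso on fragprints (L1 multiplier 0.1
by default, scikit-learn coordinate descent, tolerance 1e-6, 10⁴ max
iterations). Because L1 shrinkage is scale-sensitive, the count block is
z-scored before fitting while binary bits are left untouched; the
intercept is unpenalised, so in the infinite-penalty limit the corrected
predictor is exactly "computed + mean residual". Evaluation is
leave-one-out: each fold refits the residual model on the remaining pairs.

## Screening

Candidates pass if (1) the predicted *E* π–π* maximum lies in
450–600 nm — boundary inclusive, since a measured value of exactly 450 nm
is counted as satisfying the window in the post-screen summary — and
(2) the predicted *E* − *Z* π–π* separation exceeds 40 nm (signed; the *E*
band of azoswitches lies red of the *Z* band; an absolute-value mode is
available). Candidates without a *Z* prediction fail criterion 2 rather
than erroring, keeping screening total over arbitrary libraries. Passing
candidates are ranked by descending predicted *E* π–π* (most red-shifted
first), then descending separation — the reduction from "passes" to a
purchase list is not canonical, so the rank key is an explicit package
decision. Report MAEs are rounded to one decimal in nm. The packaged
post-screen fixture (11 commercially sourced switches, model vs
experiment) reproduces MAEs of 22.7 nm (*E*, 11 pairs) and 21.6 nm (*Z*,
10 pairs — one switch did not photoswitch and has no *Z* value) and
criteria counts 7/10/6 of 11 on the experimental values.

## Synthetic data: what it emulates and what it does not

`generate_synthetic_dataset` draws datasets from exactly the generative
model the MOGP assumes: sparse fragprint-like features (a Bernoulli bit
block and a Poisson count block, 75%/25% of the feature length), latent
task values jointly Gaussian with covariance σ_f²·T(X) across molecules
and B across tasks, iid Gaussian noise, and per-task label masking whose
defaults mirror the real label availability (≈3%, 65%, 77%, 70% missing
for the four tasks).

Feature sparsity defaults are Bernoulli(0.2) bits and Poisson(1.0) counts.
With iid features the mean pairwise Tanimoto is ≈ p/(2−p); the chosen
densities give ≈ 0.27, matching the substantial similarity of real
fragprints on a congeneric azoarene series. (Lower iid densities produce a
near-identity kernel under which signal and noise variances are nearly
unidentifiable — real fingerprint bits are scaffold-correlated, which iid
bits can only emulate at higher density.)

The generator does not emulate: chemistry-feature correlations (bits are
independent given the density), solvent structure, label noise
heteroscedasticity across sources, or any out-of-domain shift. Passing
synthetic tests therefore demonstrates correctness of the inference
machinery and the claimed statistical behaviours under the model's own
assumptions — not predictive accuracy on real photoswitches, which
requires the externally deposited curated dataset (see README).

Because rows of the label table share the molecule kernel, the cross-task
sample covariance of raw labels does not converge to B; tests whiten by
chol(T) first, after which row-iid theory applies exactly.

## Designed experiment sizes

The packaged diagnostics use problem sizes chosen a priori by a Fisher-
information (Cramér–Rao) analysis of the generator:

- Hyperparameter recovery: 200 molecules, all four labels observed,
  σ_f² = 1, σ_y² = 0.25, moderately correlated B (correlation 0.6). At the
  realistic noise default σ_y² = 0.1 the CRLB for σ_y² exceeds 20%
  relative even with every label observed, so no estimator can meet a 20%
  recovery tolerance there; at σ_y² = 0.25 the bound permits it in most
  draws. Success is judged jointly: relative Frobenius error of the
  effective amplitude σ_f²·B ≤ 20% and relative error of the
  de-standardised noise ≤ 20%. With seeds 0–9 this holds in 8/10 runs;
  the per-seed success probability is near the information-theoretic
  ceiling (~0.8), so counts fluctuate by ±1–2 across seed sets.
- Multitask advantage: 100 molecules, task correlations 0.9, one task
  trained on 12 labels and tested on the remaining 88 against a
  single-task GP trained on the same 12. The MOGP wins in 10/10 seeds.
- Bias correction: 30 pairs with a constant −19 nm computed-value shift;
  leave-one-out correction drives the signed error to ~0 and the MAE from
  19 nm to ~0.

## Known limitations

- Exact GP cost is O(N³); fine for N ≲ 2000 molecules, no sparse or GPU
  path is provided (nor needed at experimental-data scale).
- The fragment catalogue is a pragmatic 86-pattern set, not a learned or
  exhaustive vocabulary; bit-exact agreement with any particular published
  feature set is not expected, and representation comparisons should be
  read qualitatively.
- Shared σ_y² on the standardised scale implies task-dependent noise in
  nm; flip `per_task_noise` if that matters.
- The screen ranks by point predictions; predictive variances are reported
  but not used in the rank key (confidence-weighted acquisition is a
  natural extension).
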
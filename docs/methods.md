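# Methods

This note documents the models, conventions and parameter choices behind
`petqml`, in the order the pipeline runs.

## Synthetic cohorts

The generator emulates the statistical structure of PET radiomic cohorts
rather than their image content. A cohort is defined by a `CohortSpec`:

| parameter | default | meaning |
|---|---|---|
| `n_patients` / `n_samples` | — | patients; optional exact lesion count |
| `lesions_per_patient` | 80% ×1, 12% ×2, 8% ×3 | lesion-count distribution |
| `n_features` | 100 | feature columns |
| `n_informative` | 10 | features carrying class signal |
| `n_blocks` × `block_size` | 10 × 5 | redundant feature blocks |
| `rho_target` | 0.8 | within-block Spearman \|ρ\| |
| `delta` | 1.0 | standardized class-mean separation |
| `prevalence` | 0.5 | positive-patient fraction |

Labels are assigned per patient (every lesion inherits the patient's
endpoint) with the positive count fixed at `round(prevalence ·
n_patients)`. Informative features shift the class mean by `delta`
within-class standard deviations, with a random sign per feature: real
radiomic panels shift in mixed directions, and a uniform same-sign shift
would be nearly parallel to the mean vector and hence invisible to
amplitude encoding after L2 normalization. Redundant blocks are noisy
monotone transforms (identity, cube, exponential, signed power, arctan)
of one latent Gaussian parent; since Spearman correlation is invariant
under monotone maps, the latent Pearson correlation set through
ρ_s = (6/π)·arcsin(r/2) makes `rho_target` directly controllable. All
columns finally receive heterogeneous affine scales (10^U[-1,2]) to mimic
raw feature magnitudes without touching rank structure.

The three-cohort suite (121 / 84 / 335 lesions; only the 121-lesion
cohort has multi-lesion patients) uses `delta = 0.6` and prevalences
0.5 / 0.45 / 0.35, chosen so mean test balanced accuracies land in the
mid-60s-to-low-70s range typical of clinical radiomics classification.
Feature counts per cohort before reduction are not knowable from
published tables; the default of **100 features is an arbitrary
convention** and is exposed on the spec.

What the generator does *not* emulate: scanner/batch effects, missing
values, non-binary or censored endpoints, feature distributions with
point masses, and correlations *between* blocks. Passing tests therefore
demonstrate the pipeline's correctness and its behavior under controlled
signal/redundancy/noise — not clinical performance on any real cohort.

## Preprocessing

**Redundancy reduction.** Features with pairwise |Spearman ρ| ≥ SRT are
clustered as connected components of the thresholded graph (transitive:
a chain A–B–C merges even when ρ(A,C) is weak). The rule is
order-independent and deterministic. Per cluster, the highest-variance
feature survives; variance ties break by input column order; constant
features correlate with nothing and survive as singletons. Absolute
correlation is used, so strong negative correlations count as redundant.

**Selection.** Features are ranked by the R² of the univariate linear
fit of the 0/1 label on the feature — equal to the squared Pearson
correlation — computed on the fold's training rows only; the top 8 or 16
are kept.

**Scaling for encoding.** Per feature: z-score with train statistics,
then min-max to [0, 1] with train extremes (test values clipped into
range), then zero-padding to the register size and L2 normalization.
The non-negativity shift is a declared convention: it keeps amplitude
signs from encoding arbitrary centering choices. Whether to standardize
at all before encoding is a genuinely open design point; this choice is
documented rather than inferred.

## Cross-validation

"Tenfold with an 80:20 ratio" cannot be a disjoint partition (10 × 20% >
100%), so the scheme is ten independent stratified random resamples
(Monte-Carlo cross-validation). Test patients are drawn whole — all
lesions of a patient stay on one side — stratified by the patient-level
label to ~20% of lesions. The test set is then balanced exactly by
moving whole majority-class patients back to train; if a residual excess
smaller than a patient's lesion count remains, those lesions are
excluded from the fold entirely, because returning part of a patient to
train would leak patient-level information. The same fold assignments
are reused across all SRT × feature-count variants of a cohort
(harmonization), verified by hashing the assignments.

## Quantum simulation

States are exact statevectors (≤ 4 qubits in the study grid; the
simulator itself is general). The swap test's ideal ancilla-0
probability is (1 + |⟨a|b⟩|²)/2; the Hadamard test's is
(1 + Re⟨a|b⟩)/2. Hardware imperfection is modeled as a single effective
depolarizing channel per circuit, λ = 1 − (1−p1)^n1 · (1−p2)^n2 from the
circuit's one/two-qubit gate counts, then a symmetric readout flip ε,
then a binomial draw of the shot count. Defaults p1 = 5·10⁻⁴,
p2 = 5·10⁻³, ε = 0.01 give λ ≈ 0.08–0.11 on the 3-qubit swap-test
circuit — enough to displace unmitigated kernels visibly without
destroying them. Estimates are **not clipped** into range before
mitigation, so the mitigator sees the raw distortion; clipping happens
after mitigation.

Gate-count conventions (they determine λ and are therefore stated):
the state-preparation ansatz is, per layer, one Ry and one Rz per qubit
followed by a CNOT ring (2·n·L one-qubit, n·L two-qubit gates); a
swap-test evaluation counts two preparation blocks, two ancilla
Hadamards, and n controlled-swaps at 3 two-qubit gates each; a
Hadamard-test evaluation counts both preparations as controlled
(rotations become two-qubit gates, ring CNOTs become Toffoli-equivalents
at 3), which correctly makes it the deeper, noisier circuit.

State-preparation angles are fitted by L-BFGS from 8 uniform restarts
(plus the zero start), minimizing infidelity to the target; a result
above tolerance carries a warning rather than raising. The variational
classifier (qNN) trains the same ansatz by full-batch gradient descent
(default 120 epochs, learning rate 0.3, small random init) on an MSE
loss against ±1 labels, with exact parameter-shift gradients
(f(θ+π/2) − f(θ−π/2))/2, cross-checked against finite differences in the
tests.

## Classifiers

* **qsSVM** — SVC on the precomputed fidelity kernel, C = 1 fixed; the
  point of the method is the absence of hyperparameter optimization.
* **qSVM** — C from {0.01, 0.1, 1, 10, 100} by inner 5-fold
  patient-grouped CV maximizing balanced accuracy (ties → smaller C);
  the chosen C is recorded. Kernel-alignment training is out of scope.
* **qGP** — Gaussian-process *regression* on ±1 labels with kernel
  K + σ²I (σ² = 0.1), prediction = sign of the posterior mean. The
  posterior variance is computed from the test-test kernel block,
  honoring the three-kernel-evaluation structure of the hardware
  workflow. Regression-with-sign-readout is chosen over Laplace GP
  classification for determinism and closed-form algebra.
* **qNN** — as above; prediction is the sign of ⟨Z⟩ on qubit 0.
* **qDC** — 1-nearest-neighbour on d² = 2 − 2·Re⟨test|train⟩, requiring
  signed (Hadamard-test) overlaps; ties go to the lowest training index.
* **cSVM / cGP / cNN / cKNN** — RBF SVC (C = 1, median-heuristic
  bandwidth); the same GP solver as qGP on an RBF kernel, so the pair
  differs only in the kernel; a 16-unit one-hidden-layer perceptron; and
  5-NN. All consume exactly the features the quantum arm encodes
  (without the information-free zero padding), with fixed documented
  hyperparameters — no per-fold tuning, so the quantum/classical
  comparison is not confounded by unequal optimization budgets.

Noisy training kernels are symmetrized and PSD-projected (with a
warning) before any kernel machine sees them.

## Error mitigation

Calibration draws `n_pairs` (default 1000) state pairs uniformly with
replacement from train × train and records the analytic overlap and one
noisy shot estimate per pair — training states only, so no test
information reaches the mitigator. The regression is a 200-tree random
forest with inputs (noisy estimate, one-qubit gate count, two-qubit gate
count, shots), letting one model serve circuits of different depth; the
out-of-bag residual spread is reported. Regressing the final estimate
(F̂ or R̂) rather than raw ancilla probabilities is a choice; the two are
affinely related, so nothing is lost. After the entrywise map the kernel
is clipped to its valid range, symmetrized, and (fidelity kernels)
projected to the nearest PSD matrix by eigenvalue clipping — the
regression is entrywise and cannot enforce matrix-level constraints.

A property worth knowing: the depolarizing + symmetric-readout channel
acts *affinely* on kernel entries, and precomputed-kernel SVMs absorb
affine kernel distortions almost completely. At generous shot budgets
the unmitigated qsSVM therefore loses little balanced accuracy, and
mitigation's benefit appears in kernel-entry error (typically a 5–10×
MSE reduction) rather than in qsSVM BACC; the regime where mitigation
visibly protects accuracy is the scaled-down shot budget (a few hundred
shots), which the end-to-end ordering test uses. Consistently with this,
the EM-recovery checks run at 16384 shots, where the systematic bias
dominates the binomial shot floor — the regime a learned
bias-correction is built for.

## Advantage scoring and aggregation

GD_Q PSD-projects both kernels, trace-normalizes them to trace = n, and
returns sqrt of the spectral norm of √K_Q (K_C + λI)⁻¹ √K_Q with ridge
λ = 10⁻⁸·n. The classical reference is the median-heuristic RBF kernel
on the same selected, scaled training features. The direction (classical
kernel in the inverse) means GD_Q > 1 ⇔ the classical geometry cannot
reproduce the quantum one; the advantage rule is strict: GD_Q = 1 is
"unlikely". Per-variant aggregation reports each method's mean BACC over
the ten folds with the normal-approximation 95% half-width
1.96·SD/√10; qBACC/cBACC are unweighted family means. The GD_Q–dBACC
relationship is a two-sided Pearson test across variants.

## Orchestration and problem sizes

`run_full_study` executes the 18-variant grid with exact (analytic)
kernels; `run_em_study` follows the two-step hardware protocol: step 1
compares qsSVM/qGP/qDC on the designated fold (first fold, prostate-like
cohort, SRT 0.7, 8 features) across noiseless / noisy / mitigated
regimes; step 2 carries the winner (highest BACC over the noisy and
mitigated regimes; ties break qsSVM > qDC > qGP) across the first fold
of all 18 variants. qSVM and qNN stay out of the EM study — they need
many more circuit evaluations than kernel one-shot methods. Default shot
budget for noisy regimes is 2048.

The test suite and the acceptance script run everything at the sizes
above; the stochastic end-to-end checks use the first fold per seed and
a few-to-twenty seeds per claim, which keeps the whole suite in the
minutes range on one core while leaving every probabilistic assertion
several standard errors of headroom.

## Known limitations

* The noise model is a single effective depolarizing weight plus
  symmetric readout — no correlated, per-qubit, or coherent errors, no
  connectivity or transpilation effects; conclusions about mitigation
  transfer only qualitatively to hardware.
* qGP is regression-with-sign-readout, not a probabilistic classifier;
  its posterior variance is reported but unused by the decision rule.
* The qSVM optimization is a C-grid search only.
* Binary endpoints only; no multiclass, no survival modelling.
* Synthetic cohorts do not certify performance on real radiomic data
  (see the generator section for what they omit).
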
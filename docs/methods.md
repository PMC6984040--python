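# Methods

This note records the models, conventions and parameter choices behind
`rsfi`, and what the synthetic-data tests do and do not establish about
real fMRI data.

## Synthetic cohort model

Each region `k` of subject `s` at visit `v` is generated as

```
x_k(t) = a_k · r( θ_v(t) − δ_k − σ_k ) + γ · g_v(t) + ε_k(t)
```

* `r(θ)` — periodic driver, a sum of harmonics (default fundamental
  0.02 Hz with amplitude 1 and a 0.04 Hz harmonic at 0.4). Both lie inside
  the conventional resting-state band, so band-pass settings act on them
  the way they would on real slow BOLD fluctuations.
* `θ_v(t) = 2π f₀ φ_v(t)` with the monotone warp
  `φ_v(t) = t + (s/ω) sin(ωt + u_v)`, `u_v` uniform per visit, warp
  frequency 0.005 Hz, strength `s = 0.3` by default. `s < 1` guarantees
  `φ' = 1 + s·cos(·) > 0`; requests with `s ≥ 1` are rejected rather than
  emitting a non-monotone clock. The warp is what makes the signals cyclic
  rather than periodic, and what the lead matrix should be invariant to.
* `δ_k` — per-region phase offsets, evenly spaced on the circle by default;
  their sort order is the planted temporal ordering the cyclicity path must
  recover.
* `σ_k`, `a_k` — subject signature: per-region phase perturbations
  (SD = `signature_strength`, default 0.3 rad) and amplitude jitter, drawn
  once per subject and reused at both visits. They are the only
  subject-stable content, so cross-visit identification above chance is
  evidence that a feature captures them.
* `g_v(t)` — global component: white noise low-passed below 0.05 Hz,
  standardized, scaled by `global_amp` (default 0.5) and added identically
  to every region, redrawn per visit. Because it enters every row with unit
  weight, global signal regression can in principle remove it.
* `ε_k(t)` — AR(1) Gaussian noise (coefficient 0.5, stationary SD 0.3 by
  default), emulating the serial dependence of slow hemodynamic signals.

Cohort defaults mirror an imbalanced case-control study: 79 subjects, 50
labeled `patient`, two visits, one run each, 33 regions × 300 samples at
TR = 2 s. Demographics (age, sex, hearing status) are drawn per subject
with group-dependent rates and are independent of the signals, which makes
them useful as negative controls for the embedding association tests.

### Planted group effect

`inject_group_effect` alters patient records on listed ROI pairs. The
default `coupling` mode adds a pair-private oscillator at a distinct
frequency (0.03 Hz, amplitude `effect_amp`) to both regions with a phase
gap `delta` between them. The signed area is bilinear in its two arguments
and cross-frequency areas cancel over whole cycles, so the injected effect
concentrates on exactly the listed pair — which is what makes exact
support recovery by the sparse SVM a fair test. The alternative `phase`
mode shifts the pair's driver phase gap by `delta` (split
antisymmetrically); it is more physiological but necessarily bleeds into
every pair sharing one of the two regions. A zero `delta` is an identity
and is skipped.

"Large effect" in the power checks means `effect_amp = 1.5`,
`delta = 1.5 rad`, two pairs, 40 subjects (20/20) — chosen once as the
generator's definition of a clearly separable condition.

### What the generator does not emulate

No hemodynamic response convolution, scanner drift/spike artifacts, motion,
physiological (cardiac/respiratory) cycles, spatial voxel structure, or
non-stationary coupling. Consequently, green tests show the *pipeline* is
correct and well calibrated on data satisfying its assumptions; they do not
show that real BOLD data satisfy those assumptions.

## Preprocessing

Fixed order: GSR (optional) → mean-center/detrend → end-match (cyclicity
path only) → scale → band-pass (optional). Choices where the convention was
open:

* **Band-pass filter**: 4th-order Bessel, magnitude-normalized (−3 dB at
  the cutoffs), bands (0.008, 0.08) Hz baseline and (0.008, 0.2) Hz wide,
  applied forward-backward (zero phase) by default. A causal filter's
  frequency-dependent phase would distort exactly the lag structure the
  lead and time-delay matrices measure; zero-phase application preserves
  relative timing. A `zero_phase=False` switch restores causal filtering.
* **Scaling**: quadratic variation `Σ(Δx)² = 1` (discrete QV of successive
  differences), unit `l2` norm, or unit sample SD.
* **End-matching**: subtracting the linear ramp through a row's endpoints;
  closes the path for the area integral; idempotent. Note that a linear row
  end-matches to the zero row (the ramp is the row).
* **GSR**: the global signal is the across-ROI mean time course (voxel data
  never enter this pipeline), removed per row by OLS against (intercept,
  global signal), so residuals are exactly orthogonal to it. *Caveat*: OLS
  GSR absorbs an added common component `c(t)` exactly only when the
  panel's across-ROI mean is zero and `c` is orthogonal to the rows (or
  `c` is affine in the existing global signal) — in general the regressor
  itself shifts from `ḡ` to `ḡ + c` and the two projections differ at
  first order. The absorption checks therefore use a construction where
  the identity is exact (equally-spaced-phase sinusoid panel, harmonic
  common component); on generic data absorption is approximate.

## Feature conventions

* **Lead matrix**: shoelace rule over the closed polygon,
  `A[k,l] = ½ Σ_t (x_k[t] x_l[t+1] − x_k[t+1] x_l[t])` including the
  closing segment — exact for polygonal paths. Orientation is calibrated so
  a pure delay of region `l` behind region `k` gives `A[k,l] > 0`
  (`A = +π sin φ` for a cosine pair with gap `φ`), frozen by a regression
  test. Input must be end-matched; a flag end-matches internally.
* **Cyclicity spectrum**: eigendecomposition of the skew-symmetric `A`;
  the leading eigenvector is the one paired with the largest-magnitude
  eigenvalue of positive imaginary part (fixing the traversal direction),
  rotated so component 0 has phase 0. Orders are cyclic: comparisons are
  rotation-invariant. Near-ties beyond the conjugate pair are flagged and
  resolved by index; the all-zero matrix is flagged degenerate.
* **Lagged correlation**: integer lags `|τ| ≤ max_lag` (default 5 samples =
  10 s at TR 2 s, the scale of hemodynamic lags), extremum = maximum `|r|`,
  ties broken toward smaller `|τ|`. The signed `r` is stored;
  `tdm[k,l] = −τ*·TR` is positive when `l` follows `k`, consistent with the
  lead matrix. Symmetry of the LCM and antisymmetry of the TDM are exact
  because the extremum search is direction-symmetric and the lower triangle
  is derived from the upper. Optional parabolic refinement fits a 3-point
  parabola on `|r|` around interior peaks.
* **DTW**: absolute local difference by default, unconstrained alignment,
  optional Sakoe-Chiba band; numba dynamic program, each unordered pair
  computed once. The warping path is backtracked from the accumulated-cost
  matrix.
* **Vectorization**: row-major upper triangle, length `N(N−1)/2` (528 for
  33 regions); matricization restores the symmetry class (skew, symmetric
  with unit or zero diagonal).

## Fingerprinting

1-NN with cosine similarity, both directions (visit 1 gallery → visit 2
probes and vice versa); ties resolve to the lowest subject id. Reported
headline per condition is the mean of the two directional accuracies, with
both directions retained. `R_K` follows Gorodkin's formula with the
zero-denominator → 0 convention; on 2×2 tables it equals the binary MCC
identically. Robustness to GSR is the per-subject cosine distance between
with- and without-GSR feature vectors, compared across conditions with
Kruskal-Wallis and Bonferroni-corrected two-sided Mann-Whitney U tests
(Bonferroni multiplier = number of tested pairs).

## Classification

* **Splits**: Monte-Carlo CV, 100 repetitions of stratified 70/30 splits at
  the *subject* level (both visits of a subject stay together). Train size
  is `floor(0.7·n)`; per-class counts by largest remainder. Stratification
  is used because a 50/29 imbalance occasionally empties a class in
  unstratified draws.
* **Leakage policy**: standardization, PCA, VAE training and network
  fitting always use the training fold only. This is enforced structurally
  (fit objects only ever see training indices) and the augmenter is given
  training records exclusively.
* **Dimensionality**: PCA to 10 components for LDA/QDA and 20 for SVMs
  (capped by the training-set size); DA covariances are ridge-regularized
  against singularity.
* **Sparse SVM**: minimizes `(1/n) Σ hinge + λ‖w‖₁` exactly as a linear
  program (HiGHS); deterministic with exact zeros. `λ` can be chosen by
  k-fold CV on the training fold (`choose_lambda`); the power checks use
  `λ = 0.05` on standardized features. `‖w‖₁` is provably non-increasing
  in `λ`; support *cardinality* follows suit except near `λ → 0`, where LP
  optima are non-unique and the support can blip.
* **VAE augmenter**: two fully-connected layers per side (256/64 default),
  2-D Gaussian latent, MSE reconstruction + KL latent loss, Adam, early
  stopping on the training loss; trained per class on standardized
  vectors, samples mean-adjusted and re-scaled to the class moments, and
  matricized samples inherit the feature kind's symmetry by construction.
* **CNN**: 1×N convolution stage (shared filter row applied to every
  matrix row), N×1 stage collapsing rows, dense layer with 0.5 dropout,
  2-way softmax; numpy forward/backward with Adam. Default sizes 16/32/64
  filters/units — deliberately small for cohorts of tens of subjects; all
  sizes are constructor arguments.
* **Null calibration**: label-shuffled accuracy is compared to the class
  prior with a binomial band whose `n` is the number of independent
  (subject × shuffle) units, not the number of test predictions:
  repetitions within one shuffle share the panel and are strongly
  dependent. Shuffled-label CV on a fixed balanced cohort also carries a
  small negative bias (sampling-without-replacement dependence between
  train and test composition), so null means sit slightly below the prior;
  the band above accommodates this at the cohort sizes used.
* A maximum-margin *linear* SVM on a 4-blob XOR layout legitimately reaches
  up to 75% (it can capture 3 of the 4 blobs); the kernel-separation test
  asserts the substantive gap to the rbf kernel rather than an idealized
  50%.

## Embedding diagnostics

t-SNE (PCA initialization, seeded; default perplexity 30, must be below
`n/3`) and Isomap (default 10 neighbors). The visually motivated "two
clusters" notion is formalized as 2-means on the embedded coordinates;
categorical metadata are tested against cluster labels by chi-squared,
continuous metadata by Mann-Whitney U, Bonferroni-corrected over fields.
Isomap reproduces planar geometry exactly only with a complete
neighborhood graph (`k = n−1`), which the corresponding invariant test
uses.

## Problem sizes

The test suite and acceptance script run cohorts of 40 subjects (33
regions × 300 samples) for fingerprinting and classification, 20-seed
ensembles for ordering recovery and chance baselines, 100 Monte-Carlo
repetitions (5 shuffles × 20 splits) for null calibration, 3000-sample
dense panels for the reparameterization probe, and 200 short random pairs
for DTW-oracle equivalence — sizes at which every stochastic check is
stable across seeds while the full suite stays fast on a single CPU.

## Known limitations

* The generator's cyclic driver is shared across regions up to phase; real
  regions mix multiple latent processes.
* One run per visit is generated by default; the policy for combining
  multiple runs per visit into one feature (averaging of vectorized
  features) is a package choice, exposed rather than prescribed.
* GSR absorption is exact only in the documented regime; on generic data
  GSR changes features at first order in the global component's overlap
  with the rows.
* The CNN and VAE are intentionally small stand-ins for connectome-style
  architectures; they demonstrate calibration and augmentation mechanics,
  not state-of-the-art classification.
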
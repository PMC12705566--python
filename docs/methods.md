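# Methods

## The measurement and its artifacts

An EEM records fluorescence intensity I(λ_ex, λ_em) on a rectangular grid
(default Ex 220–550 nm step 5, Em 240–750 nm step 1; 67 × 511 = 34,237
cells). Three instrument artifacts overlay the chemical signal: first-order
Rayleigh scatter on the diagonal em = ex, second-order Rayleigh on
em = 2·ex, and the water Raman band displaced from the excitation line by a
fixed wavenumber shift. The Raman ridge position follows
1/λ_em = 1/λ_ex − Δν̃·10⁻⁷ with Δν̃ = 3400 cm⁻¹ (the O–H stretch); at
Ex 350 nm this puts the band near 397 nm. Emission below the excitation
wavelength is non-physical (anti-Stokes at the intensities involved) and is
zeroed.

## Preprocessing

Stage order is fixed: mask → interpolate → smooth → zero → clip.

- **Masking.** A cell is scatter iff |em − ex| ≤ w₁ or |em − 2ex| ≤ w₂ or
  |em − raman(ex)| ≤ w_R. Defaults w₁ = w₂ = 15 nm, w_R = 10 nm. The source
  protocol names the operations but not the band widths, so these are
  package defaults chosen from common EEM practice and exposed in
  `ScatterConfig`; reproducibility requires explicit numbers.
- **Interpolation** runs along each emission row only (scatter ridges cut
  across emission at fixed excitation): masked runs are filled linearly
  between their unmasked neighbours, edge runs by nearest-value extension.
  A fully masked row is an error naming its excitation wavelength rather
  than a silent fill.
- **Smoothing** is a centered moving average (default window 11 points)
  with shrinking windows at row edges, so row length, row minima and row
  maxima are preserved as bounds.
- **Zeroing** sets cells with em < ex + margin (default margin 0) to zero
  *after* interpolation so filled values cannot leak into the triangle;
  negatives (possible in raw noisy input) are clipped last because
  fluorescence is non-negative.

Not modelled, deliberately: inner-filter correction, Raman-unit
normalization and blank subtraction — none is part of the emulated protocol.

## Peak features

Seven conventional peak regions are quantified per sample: A (260/400–460,
UV humic acid), M (290–310/370–410, marine humic acid), C (320–360/420–460,
visible humic acid), D (390/509, fulvic acid), B (275/305, tyrosine-like),
T (275/340, tryptophan-like), N (280/370, phytoplankton-related). The
regional statistic is the window **mean** (robust to single-pixel noise;
window max is available as a config alternative), with point positions
snapped to the nearest grid line and treated as one-cell windows. Both the
per-window statistic and across-sample group summaries are computed, since
"mean intensity" is ambiguous between the two readings.

## Non-negative PARAFAC

The study tensor X (sample × excitation × emission) is intrinsically
trilinear: each fluorophore contributes an outer product of its excitation
spectrum, emission spectrum and per-sample concentration. The model
X_ijk ≈ Σ_f a_if b_jf c_kf is fitted with non-negativity on all three modes
(spectra and concentrations are physical quantities) by alternating least
squares; each mode update solves exact per-row NNLS subproblems through the
Gram matrix and its Cholesky factor, so the residual is non-increasing at
every iteration (asserted in tests). Scale indeterminacy is resolved by
unit-norm spectral loading columns with magnitudes absorbed into the scores.

Numerical choices: the first start is a non-negative HOSVD initialization
(absolute leading singular vectors per mode), the rest uniform-positive
random — 10 starts by default for a production fit, each screened for 60
iterations; the two best screened candidates are refined to convergence
(relative fit-error change below 10⁻⁸, at most 500 iterations) and the
better refined solution wins. Refining two candidates matters because EEM
components with nearly collinear emission spectra create degenerate ALS
basins whose early iterates can out-screen the basin that ultimately fits
better. A 10⁻¹² ridge stabilizes the Gram Cholesky. The rank-diagnostic
paths (`split_half`, `select_rank`) use 8 restarts with 80 screening
iterations — they meet the hard half-sample refits where a merged-component
basin is a frequent trap, so they spend more on exploration than the
production fit. The emission axis may
be decimated (default 4× in the pipeline) before ALS; the spectral loadings
are smooth on a 1 nm grid, so decimation changes little except run time.

Rank selection combines two diagnostics:

- **CORCONDIA**: the least-squares Tucker core G for the fixed loadings is
  compared with the superdiagonal identity core T;
  100·(1 − ‖G − T‖²/‖T‖²) stays near 100 at an appropriate rank and
  collapses (often far below zero) when over-factored. For F = 1 the value
  is 100 by definition; with active non-negativity constraints the
  least-squares core can deviate microscopically, so the single-component
  case is special-cased to the definitional value. Rank-deficient loadings
  return NaN (a failure flag) instead of raising.
- **Split-half analysis**: random sample halves are fitted independently,
  components matched greedily by Tucker congruence (cosine similarity) on
  concatenated excitation+emission loadings, and 100 × the mean matched
  congruence reported, minimized over 3 random splits (the worst split is
  the honest number). The acceptance bar is 95 %.

The chosen rank is the **largest** candidate clearing both thresholds
(split-half ≥ 95, core consistency ≥ 60; the latter threshold is a package
choice, documented here because no standard value exists). An empty
admissible set returns the smallest candidate with a warning flag.

Held-out samples are scored against fixed loadings by the same NNLS
machinery (`project_scores`), which is linear in the sample.

## Attention classifier

The classifier is a deliberately small vision-transformer-style network,
implemented in NumPy with hand-written backpropagation:

- **Patching.** 2-D EEMs are zero-padded up to multiples of the patch size
  (default 8 × 32 → 9 × 16 = 144 patches on the default grid) and cut into
  non-overlapping flattened blocks; 1-D emission spectra use windows of 16
  (→ 32 tokens for 511 points); feature vectors (7 peaks or 5 PARAFAC
  scores) enter as a single token so all three views share one code path.
- **Architecture.** Linear patch embedding to d = 64, learned additive
  positional encoding, a prepended classification token, then depth-2
  pre-norm encoder blocks: layer norm → multi-head attention (4 heads,
  softmax(QKᵀ/√d_k)V per head, concatenated and output-projected) →
  residual; layer norm → 2-layer GELU MLP (hidden 128) → residual. The
  class token feeds layer norm → GELU MLP head with dropout → class logits.
  Layer normalization (not batch normalization) keeps per-token statistics
  independent of batch composition.
- **Training.** Cross-entropy with Adam (learning rate 3·10⁻³, batch 32,
  80 epochs by default), dropout 0.1, inputs standardized with training
  statistics (per-feature for feature views, global for spectra). Optional
  early stopping monitors loss on an internal stratified hold-out (20 %,
  patience 15) and restores the best snapshot; it activates only when every
  class has at least 5 training samples. Everything is deterministic given
  the config seed, and dropout is off at inference, so repeated prediction
  is bit-stable. Gradients are verified against finite differences in the
  test suite.

These sizes are matched to studies of a few hundred spectra; a larger model
would memorize before it generalizes. Baselines (KNN, k = 5; random forest,
200 trees) consume flattened vectors and expose the same
probability-vector contract.

Class labels are the three concentration levels **within one polymer**
(control spectra shared across tasks), matching the per-polymer three-class
design of the emulated study; a joint 7-way task is out of scope.

## Evaluation

Splits are stratified by class: default 2/3 calibration, 1/3 validation,
with 5-fold stratified cross-validation folds available on the calibration
part (the emulated study names the three sets without stating ratios; these
defaults are recorded in the config). Metrics are one-vs-rest: sensitivity
of class c is TP_c over the true count of c; specificity counts false
positives **column-wise** (predictions into c from other true classes),
TN_c/(TN_c + FP_c); accuracy is trace/total. This column-wise convention is
the only one consistent with all published per-class worked-example cells,
which the test suite reproduces exactly. Accuracy equals the
prior-weighted mean of sensitivities (asserted as an identity test).

The excitation sweep trains an independent 1-D classifier on the emission
slice at each requested excitation wavelength and reports the validation
accuracy curve; on synthetic data whose discriminative component is excited
near a known wavelength, the curve's maximizers concentrate around it.

## Shapley attribution

The explained quantity is the predicted probability of a target class
(the true class in the pipeline) — chosen over the logit for
interpretability. The value of a feature coalition S is the model output on
the explained instance with features outside S replaced by the
calibration-set feature means (single-reference masking, deterministic).
Exact values enumerate all 2^p coalitions for p ≤ 15 (vectorized into a
single model call); beyond that a seeded Monte-Carlo permutation estimator
reports values with per-feature standard errors. Efficiency, dummy and
symmetry hold exactly in exact mode and are asserted against a brute-force
all-orderings oracle for p ≤ 5. Rankings aggregate mean |φ| per feature,
overall and conditioned on the true class, with ties broken by catalog
order.

## Synthetic data generator

The generator *defines* the study conditions for every test:

- **Components.** Five separable Gaussian fluorophores at the resolved
  component positions 305/425, 285/355, 375/475, 360/430 nm plus one broad
  long-wavelength component (420/545 nm) standing in for the composite
  fifth component; σ 15–30 nm (45 nm emission for the broad one) so the
  seven peak windows capture distinct mixtures. Gaussian (not log-normal)
  profiles keep the noise-free tensor *exactly* trilinear — testability
  outranks spectral realism here.
- **Treatment.** Multiplicative loading factors per (component, polymer,
  dose): low dose in [0.6, 0.9] (below control), high dose in [1.2, 1.8]
  (above control), strength ordered PS > PVC > PET, control fixed at 1.
  These bands implement the dominant reported pattern; sign reversals for
  individual components are configurable but not default.
- **Noise.** Per-sample-and-component log-normal biological scatter
  (σ = 0.10) and additive Gaussian measurement noise (σ = 2 intensity
  units against component amplitudes of 400–900, i.e. SNR well above 20),
  plus Gaussian-profile scatter ridges (amplitudes 1500/400/250 for
  Rayleigh 1/2 and Raman, width 6 nm). The defaults put the study in the
  well-separated regime the emulated experiment reports (its classifiers
  approach 100 % accuracy), so classification tests certify the pipeline,
  not a hard statistical frontier.

What the generator does **not** emulate: inner-filter effects, pH and
quenching chemistry, instrument drift, correlated (non-separable) fluorophore
shapes, and label noise. Passing tests therefore demonstrate correctness of
the algorithms under the stated statistical model, not field performance on
real exudate spectra.

## Problem sizes

Module tests run on reduced grids and 6–16 samples per group; the rank
diagnostics are exercised at the full 336-sample design with the emission
axis decimated 4×, and the end-to-end reproduction defaults to 16 samples
per group at `scale="small"`. These sizes are the package's desk-scale
choices; all are configurable upward.

## Known limitations

- ALS with non-negativity can hit local minima; multi-start screening
  mitigates but does not eliminate this, and degenerate (collinear)
  solutions at over-specified ranks are reported through the diagnostics
  rather than prevented.
- The CORCONDIA core is computed by pseudo-inverse, which is exact for the
  unconstrained least-squares core but ignores the non-negativity of the
  fitted loadings.
- The transformer trains on CPU in NumPy; it is sized for hundreds of
  samples and is not a general-purpose deep-learning stack.
- Exact Shapley is exponential in p and hard-capped at 15 features.
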
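# Methods

This note documents the models, estimators and numerical choices behind
`megsync`, and what the synthetic-data tests do and do not establish about
real MEG data.

## Time-frequency decomposition and PLV

**Wavelet.** The transform uses a complex Morlet kernel with a constant
number of cycles per wavelet (default `n_cycles = 7`), so bandwidth scales
with center frequency (constant Q). The Gaussian envelope is truncated at
3 SD and the kernel mean is subtracted exactly, so a constant signal
produces coefficients below 1e−8 everywhere. A real-valued kernel (e.g. a
Mexican hat) cannot produce an instantaneous phase, so a complex constant-Q
kernel is the only self-consistent choice for phase-locking analysis.

**Edge handling.** Coefficients within half the kernel support of either
epoch boundary are flagged invalid; PLV averages only valid samples.
Unmasked edges would bias PLV upward (edge coefficients correlate across
signals through the shared window). At the default 7 cycles, a 1 Hz wavelet
spans ±3.34 s, leaving ~3.3 s of valid samples in a 10 s epoch; in 5 s
epochs 1 Hz is fully masked, which is why the reduced-scale grid starts at
2 Hz. A fully masked frequency is reported as missing (NaN), never as zero.

**PLV estimator.** Within each epoch, the relative phase is
`angle(W_x · conj(W_y))` wrapped to (−π, π], and PLV is the modulus of the
mean unit phasor over all valid samples (no decimation). Per-epoch PLVs are
averaged arithmetically across epochs. The estimator is symmetric in its
inputs, bounded in [0, 1], and has a positive finite-sample floor of order
`sqrt(π/4N_eff)` for N_eff effectively independent phase samples — visible
in the tests as a monotone decrease of the white-noise floor with signal
length.

**Frequency grid and bands.** The default grid is geometric: 30 points
from 1 to 75 Hz (consecutive ratio 75^(1/29) ≈ 1.1605). Bands partition the
grid as δ [1,4), θ [4,8), α [8,14), β [14,28), lower γ [28,75]; boundary
frequencies go to the higher band. Band-central wavelets are the grid
points nearest 2, 6, 11, 23 and 48 Hz (ties to the lower frequency;
out-of-range targets clamp to the endpoints).

## Synthetic cohort generator

The generator is a first-class, tested component: it defines the study
conditions under which every downstream claim is verified.

**Coupling model.** Each planted pair follows a driver–response scheme in
signal space: region i carries a narrowband stochastic driver c(t); region
j mixes it with an independent process, `x_j = κ·c + sqrt(1−κ²)·b`. The
drivers are unit-SD oscillations with Ornstein–Uhlenbeck phase jitter
(SD 2.2 rad, correlation time 0.1 s) confined to a constant-Q band
(Butterworth edges f/1.25 … f·1.25, zero-phase). The jitter dephases
independent drivers, setting the κ = 0 PLV floor (≈ 0.13 for 10 s epochs at
alpha frequencies); the band-pass keeps planted couplings
frequency-specific — without it, jitter sidebands spread coherent energy
across the whole spectrum and every band classifies the groups. Because the
wavelet transform is linear, the expected PLV of a planted pair has the
closed form

    E[PLV](κ) = (1/2π) ∫ (κ + s·cos a) / sqrt(1 + 2κs·cos a) da,   s = sqrt(1−κ²),

strictly increasing from 0 (κ = 0) to 1 (κ = 1); measured values at
10 s / 600 Hz are ≈ 0.13 / 0.25 / 0.49 / 0.83 at κ = 0 / 0.3 / 0.6 / 0.9
(the floor adds in near κ = 0). Phase-domain alternatives (a shared Wiener
or OU phase driver with mixing weight κ) were rejected: at the jitter
strength needed for a sub-0.15 floor their κ→PLV map is nearly flat below
κ ≈ 0.5, leaving no usable mid-range contrast. Amplitudes of the two
regions remain essentially uncorrelated; coupling is carried by phase.

**Cohort assembly.** Each subject × epoch: planted components are summed
into their regions (a region in several pairs receives several components),
plus 1/f pink background noise amplitude-matched to the drivers
(`noise_sd = 1.0`, spectral exponent 1.0). Per-subject coupling strengths
are `κ_s = clip(κ_group + N(0, 0.1), 0, 1)`, giving between-subject
variability that the clinical covariates inherit.

**Fast tensor path.** `simulate_plv_tensor` skips signal synthesis and
draws PLV cells from Beta distributions with mean
`floor + (1−floor)·E[PLV](κ_s)` on planted cells (floor 0.14, the
finite-sample level of the signal path at study scale) and the floor
elsewhere; the concentration parameter (ν = 60) emulates epoch-averaging
variance. Means are clipped to [1e−3, 1−1e−3] to keep Beta parameters
valid when κ_s clips at 1. Both paths share the same metadata model, so
classification/PLS tests can use the cheap path without changing the
planted structure.

**Clinical covariates.** Patients' severity scores follow
`max(0, 20 + 120·dev + N(0, 12))` and symptom scores
`max(0, 9 + 40·dev + N(0, 4))`, where dev is the subject's realized
alpha-coupling deviation from the configured group mean — matching the
target moments 20 ± 19 and 9 ± 6 while coupling scores positively to
connectivity. Days since injury (patients only) are uniform on [3, 90] days
rank-remapped through a Gaussian copula to correlate −0.5 with alpha
coupling.

**What the generator does not emulate.** Volume conduction and field
spread, amplitude–amplitude coupling, non-stationarity across epochs,
head-motion artefacts, realistic cross-frequency structure, or spatially
structured (atlas-geometry-aware) effects. Passing tests therefore show
that the estimators recover planted phase-coupling structure under
controlled conditions — not that real mTBI data would yield the same
accuracies.

## Classification pipeline

- **Ranking.** Per-feature Mann–Whitney AUC via average ranks (ties count
  1/2; a constant column scores exactly 0.5), folded as max(AUC, 1−AUC)
  because a feature discriminating in either direction is useful to a
  linear model. Ties in the ranking break by column order (lower frequency,
  then lower pair index) for bit-reproducibility.
- **Classifier.** Soft-margin linear SVM (`sklearn.svm.SVC`,
  `kernel="linear"`), default C = 1.0 (unspecified in the emulated
  analysis; exposed in config). Feature columns are z-scored with
  training-fold statistics only — unscaled PLVs across frequencies would
  otherwise dominate by variance.
- **LOOCV.** Ranking, standardization and fitting see only the training
  fold; the held-out subject is never touched (enforced by construction and
  by an outlier "leakage canary" test). Confidence is the signed Euclidean
  distance (ωᵀx+b)/‖ω‖, comparable across folds with different ‖ω‖;
  positive = patient side, so a misclassified patient carries a negative
  distance.
- **Permutation null.** Each label shuffle re-runs the full nested
  procedure, including per-fold re-ranking — the only unbiased reading of
  "repeating the same procedure". p uses the add-one estimator
  (1 + #{null ≥ observed})/(n_perm + 1), so p is never zero and the null
  is valid under ties.
- **k-curve.** One LOOCV per k = 1..k_max reuses the per-fold ranking
  (computed once per fold) and refits the SVM per k; the best k takes the
  smallest k on ties.
- **Robustness map.** For a band's wavelets and folds, a connection scores
  −1 in each (fold, wavelet) cell where any of its features was selected,
  0 otherwise; the map is the mean (−1 = always selected).

## PLS

- **Contrast PLS** uses the standard mean-centered form: group means of
  each element, centered on the grand mean of group means, decomposed by
  SVD. With two groups the centered matrix has rank 1: a single latent
  variable whose left vector is the antisymmetric group contrast. The SVD
  sign is fixed so the patient block carries the non-positive left weight;
  elements elevated in patients then load negatively, putting
  patient-hyperconnectivity in the negative bootstrap-ratio tail and
  control-dominant coupling in the positive tail.
- **Behavioural PLS** uses per-element Pearson correlations with the
  covariate as the cross-block (one row → one LV) and additionally reports
  the overall correlation between LV-projected brain scores and the
  behaviour. It is run on the patient block by default (the covariate
  exists only there), with `rows` exposed for other choices.
- **Permutation test.** Contrast: rows permuted across groups; behavioural:
  covariate shuffled. p per LV index with the add-one estimator. Exact ties
  occur when a permutation reconstitutes the observed split, so the
  1/(n_perm+1) floor is attained only up to reconstitution probability.
- **Bootstrap ratios.** Subjects resampled with replacement within groups;
  resamples that collapse a group below two distinct subjects are redrawn
  (capped). Each resample's loadings (singular value × saliences) are
  sign-aligned to the original salience vector by dot product — adequate
  for a single LV, cheaper than Procrustes. Ratio = original loading /
  bootstrap SE (ddof 1); zero-SE elements are flagged NaN, not infinite.
- **Tails and proportions.** Tail thresholds are linear-interpolation
  quantiles of the pooled finite ratios; ties at a threshold fall inside
  the tail. Per-frequency counts above/below feed pooled-variance
  two-sample proportion z-tests (no continuity correction; zero pooled
  variance returns p = 1 by convention).

At the reduced desk scale, the omnibus behavioural permutation test is
underpowered (10 planted elements among 792; the singular value is
dominated by chance correlations at n = 20), while the element-level tail
analysis recovers the planted alpha pattern reliably. The acceptance script
reports the honest omnibus p alongside the tail counts.

## Reproducibility and scale

A single global seed fans out to per-stage seeds via
`numpy.random.SeedSequence(seed).spawn` in a fixed stage order, so stages
are independently re-runnable; reruns of an identical config reproduce
every numeric artifact bit-for-bit (checked by manifest digests). All
tie-breaks are deterministic and documented.

The test suite and acceptance script run at a reduced scale chosen once: 12
regions (66 pairs), a 12-point grid from 2 to 60 Hz, 5 epochs of 5 s at
150 Hz, ten planted alpha pairs at κ = 0.8 (patients) vs 0.3 (controls),
cohorts of 20 per group (40–41 subjects). The full 90-region, 30-frequency,
27 × 10 s configuration is reachable through `SimulationConfig` defaults.

## Region metadata

The packaged AAL-90 table (names, MNI centroid coordinates, lobe grouping,
display order; left/right homologues adjacent, ordered Frontal → Temporal →
Limbic → Parietal → Occipital) is used only for labeling and matrix
ordering — coordinates never enter any computation.

## Known limitations

- Absolute PLV levels depend on `n_cycles`, the edge mask and the epoch
  length; cross-study comparisons should fix these.
- PLV does not distinguish true lagged coupling from zero-lag field spread;
  no leakage correction (e.g. imaginary coherence, PLI) is implemented.
- The linear SVM's C and the feature standardization policy change absolute
  accuracies; results should be reported with the C used.
- Behavioural PLS supports a single covariate; no multi-behaviour blocks,
  split-half reliability, or rotated variants.
- The generator's clinical-score model is linear with truncation; only the
  first two moments of the emulated score distributions are matched.
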
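# Methods

## Problem and model

Spike-wave discharges (SWDs) in absence epilepsy can leave behavior intact
("spared") or abolish responsiveness ("impaired"), and the distinction is
invisible without concurrent behavioral testing. The package classifies
individual SWDs from EEG alone, under a safety-asymmetric objective: a
discharge (or a patient) may only be called spared if the classifier is
certain — the target is a spared predictive value of 100% (zero
false-spared), with sensitivity maximized subject to that constraint.

The pipeline is:

1. harmonize recordings onto a 16-channel 10–20 montage at 256 Hz, band-pass
   0.5–min(100, Nyquist−1) Hz, common-average reference;
2. cut a preictal window `[onset − pre, onset)` and an ictal window
   `[onset, onset + ict)` per discharge (defaults 1000 ms / 500 ms);
3. extract features per window — basic (spike-band power 15–50 Hz, wave-band
   power 2.5–6 Hz, duration on the ictal window), extended (Hjorth
   parameters, RMS, six canonical band powers, voltage and
   instantaneous-power moments, multiscale permutation entropy), and CSP
   log-variance features;
4. screen non-CSP features with a two-sided Wilcoxon rank-sum test at
   p < 0.001 (inside each training fold by default);
5. score with LDA or a linear SVM; for the fusion strategy, combine the two
   window scores with weighted Bayesian fusion; calibrate a conservative
   threshold τ;
6. evaluate by stratified 10-fold cross-validation pooled across folds, and
   at patient level by the rule "impaired if any SWD is impaired".

The model grid is 4 feature sets × 4 window strategies × 2 classifiers = 32
configurations.

## Common spatial patterns

Per-epoch spatial covariances are normalized by trace and averaged per class
into C_s and C_i. Filters solve C_i w = λ (C_s + C_i) w; λ ∈ [0, 1] is the
impaired share of the composite variance along w, and filters are ranked by
max(λ, 1−λ), which allows an odd filter count (default k = 5 per window, so
the CSP feature vector over both windows has 10 entries). The eigensolver
returns filters orthonormal in the composite metric (W(C_s+C_i)Wᵀ = I); a
rank-deficient composite is ridge-regularized by 1e-8·trace/channels with a
warning. Features are f_j = log(var_j / Σ_j' var_j'), invariant to global
window rescaling. A dedicated test cross-checks the eigensolve against an
independent whiten-then-diagonalize construction.

## Weighted probabilistic fusion

Each window's scalar score gets class-conditional Gaussian likelihoods
(maximum-likelihood fit on training scores; σ floored at 1e-6 of the score
range). The fused impaired-score is the weighted log posterior ratio

    α·log N(s_pre; μ_pre,c, σ_pre,c) + (1−α)·log N(s_ict; μ_ict,c, σ_ict,c)
    + log π_c,   differenced impaired − spared,

with empirical class priors π. α runs over {0, 0.01, …, 1}; each candidate
is evaluated by pooled spared predictive value under an inner stratified
5-fold CV of the training scores (each inner fold refits Gaussians and the
threshold), tie-broken by spared sensitivity and then by the smaller α. At
α ∈ {0, 1} fusion reduces exactly to the single-window posterior ranking.
On well-separated synthetic data the inner search frequently returns α = 0:
the ictal window alone is already perfect there, and the tie-break prefers
the smallest weight.

## Conservative calibration

Zero false-spared on the calibration data is enforced by construction:

    τ = min_impaired − margin − gap_fraction · max(0, min_impaired − max_spared)

and "spared" is predicted only below τ. Any gap_fraction in [0, 1] keeps
every impaired calibration example at or above τ. The default
gap_fraction = 0.5 centers τ in the empirical separation gap. The edge rule
(gap_fraction = 0) places τ exactly at the impaired sample minimum, so on
exchangeable held-out data roughly 1/n_impaired of new impaired examples
fall below it no matter how separated the classes are — an order-statistic
leak that defeats the purpose of the calibration; centering τ in the gap
removes it whenever a gap exists. `margin` (default 0) subtracts a further
fixed safety offset. Every fitted bundle asserts zero false-spared on its
own calibration data after fitting.

## Feature definitions and numerical choices

* Band powers integrate a Welch PSD (Hann, 50% overlap, segments up to 4 s;
  short windows fall back to a single segment) over the band; the spike band
  is 15–50 Hz and the wave band 2.5–6 Hz so the 2.5–5 Hz fundamental and its
  sharp-transient harmonics separate cleanly. Units are µV²; only internal
  consistency matters downstream.
* Hjorth mobility uses the per-sample first difference, so a sampled
  sinusoid at frequency f has mobility 2·sin(πf/fs) exactly; complexity is
  the mobility of the difference over the mobility of the signal; a constant
  channel gets mobility = complexity = 0.
* Moments: kurtosis is non-excess (Gaussian → 3).
* Multiscale permutation entropy: order 4, delay 1, scales 1–3
  (non-overlapping averaging), natural log, ties broken by temporal
  position; range [0, ln 24], 0 for a strictly monotone signal.
* Scalar features are computed per channel and averaged across channels; a
  per-channel variant is not exposed.
* Windows are half-open with the onset sample belonging to the ictal window;
  events too close to the recording start are excluded with a warning, never
  zero-padded. Sample counts are round(len_ms · rate / 1000).
* The ictal window is fixed-length even when the discharge is shorter.

## Synthetic cohort

No public recordings of this kind exist, so the generator fabricates the
study conditions: 130 SWDs (81 spared, 49 impaired) across 34 patients at
256 Hz on the 16-channel montage. Each SWD is a 3.5 Hz sinusoid (±3%
per-event jitter) with a Gaussian-windowed ~20 ms transient on each wave
peak, a 150 ms cosine on/off ramp, scaled by a scalp topography and added to
1/f background noise (15 µV RMS) with a 10 Hz posterior alpha rhythm. A
2 s Hann-enveloped 2 Hz component precedes each onset (preictal delta).

Class contrasts mirror the published labeled cohorts:

* durations: lognormal, spared mean 947 ms / SD 414 ms, impaired mean
  4336 ms / SD 3269 ms (SDs recovered from the published standard errors and
  class sizes), truncated to [300 ms, 20 s];
* wave amplitude 40 µV (spared) vs 80 µV (impaired), i.e. ~4× wave power;
* preictal delta amplitude gain 2.0 for impaired (~4× delta power);
* topography: spared discharges are anterior-dominant; impaired are shifted
  toward the posterior mirror profile (shift 0.6, RMS-matched). Without a
  topographic difference the classes differ only along one shared spatial
  direction and, after per-epoch trace normalization, the class-independent
  noise directions outrank it in max(λ, 1−λ) — the selected filter set then
  carries no class information. Distinct topographies are also what the
  clinical description of the two classes reports.
* per-event amplitude jitter is uniform ±10% (compact support). With
  Gaussian jitter the impaired score distribution has an unbounded left
  tail, and a zero-false-discovery calibration cannot hold out of fold on
  any data; the bounded choice emulates the empirical separability the
  clinical cohorts must have had for the published operating point to
  exist.

What the generator does **not** emulate: artifacts (blinks, EMG), non-SWD
epileptiform patterns, inter-patient montage/rate heterogeneity beyond what
`preprocess` harmonizes, volume-conduction correlation of the background
noise, or any physiological thalamocortical dynamics. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline under the stated contrasts, not clinical performance.

Patient assignment is round-robin after a seeded shuffle; an optional
`patient_purity` parameter partitions patients by class for patient-level
validation scenarios. Identical (config, seed) pairs reproduce recordings
bit-for-bit.

## Evaluation choices

Cross-validation is stratified at the SWD level (the per-patient grouping
mode is available via `group_by_patient=True`); folds are pooled into one
confusion table with spared as the positive class, and per-fold counts are
retained. Undefined ratios (0/0) surface as NaN. Feature selection defaults
to per-fold scope; a `global` scope reproducing whole-dataset selection is
available but leaks test information into the screen and is not the
default. Window grid search ranks (pre, ict) cells by spared predictive
value, then spared sensitivity.

Problem sizes in the test suite: the default 130-SWD cohort for the
end-to-end experiment and a 40-SWD cohort for unit-level checks; the
permutation-null and grid-search checks use reduced fold counts and shuffle
replicates, sized so the whole suite runs in about a minute.

## Known limitations

* The fusion Gaussians are fit on in-sample training scores, which
  underestimates their spread slightly; the inner CV in the α search is the
  guard against choosing a fragile weight.
* The conservative threshold transfers across cohorts only to the extent
  the score scale does; `external_validate` refits nothing on the test
  cohort by design.
* The rank-sum screen applies no multiple-testing correction; the p < 0.001
  criterion is a raw per-feature threshold by design.
* Cz re-referencing is not available after reduction to the 16-channel
  subset (no Cz channel); re-reference before subsetting instead.
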
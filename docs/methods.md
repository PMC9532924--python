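# Methods

`eegsync` implements a complete analysis path for predicting which
children with drug-resistant epilepsy will respond to vagus nerve
stimulation (VNS) from pre-implantation scalp EEG and baseline clinical
covariates: phase-synchronization feature extraction, responder /
non-responder group statistics, and a nested cross-validated linear SVM.
Because no patient data ship with the package, a first-class synthetic
cohort generator with known ground truth backs every stage.

## Phase-synchronization metrics

For two narrowband signals with instantaneous phases φ_a(t), φ_b(t)
(arguments of the Hilbert-transform analytic signals) and phase
difference Δφ(t) = φ_a − φ_b wrapped to (−π, π]:

* **PLV** = |⟨e^{iΔφ(t)}⟩_t| — modulus of the time-averaged unit phasor.
  1 when Δφ is constant; 0 in expectation when Δφ is uniform on the
  circle. Sensitive to volume conduction: a zero-lag common source makes
  Δφ ≈ 0, which PLV cannot distinguish from genuine locking.
* **PLI** = |⟨sign Δφ(t)⟩_t| with sign(0) = 0 — the asymmetry of the
  phase-difference distribution around zero. Constant nonzero, non-π lags
  give 1; zero-lag (volume-conducted) coupling gives 0. The sign(0) = 0
  convention makes the PLI of a signal against itself exactly 0.
* **wPLI** = |⟨Im S(t)⟩_t| / ⟨|Im S(t)|⟩_t, S = a·conj(b) the
  per-sample cross-spectrum — the imaginary-magnitude-weighted variant
  that softens the PLI's discontinuity near 0/π lags. The non-debiased
  population form is used. When Im S vanishes identically (strict zero
  lag; numerically, below 10⁻¹² of |S|) the ratio is undefined: 0 is
  returned and a degeneracy warning logged so zero-lag fixtures flow
  through the pipeline rather than crashing it.

### Estimation modes and finite-sample bias

The default estimator (`hilbert_mode="epoch"`) band-pass filters and
Hilbert-transforms each 2-s epoch, trims 10 % of samples from each epoch
edge (Hilbert edge ripple), computes each metric per channel pair per
epoch, averages over epochs, then averages (unweighted) over all
unordered pairs — the "mean global" value. An alternative
(`hilbert_mode="whole"`) transforms the continuous record and treats it
as a single long epoch.

The two differ in bias: per-epoch estimates of *uncoupled* signals carry
a positive floor of roughly sqrt(π / (4·n_eff)), where n_eff is the
number of phase decorrelation times per 2-s epoch — about 0.2–0.45
depending on band. The whole-series estimator's floor shrinks with total
duration instead. Consequently the identities "metrics → 0 for
independent signals as duration grows" and "PLI/wPLI < 0.1 under
zero-lag mixing at 60 s" hold for — and are tested in — whole-series
mode, while group comparison and modeling use the per-epoch default
(the per-epoch floor is common to both groups and cancels from the group
contrast). Per-epoch and whole-series agree for strictly stationary
locked signals up to the residual edge ripple (~10⁻³ on PLV).

## Preprocessing

Recordings are polyphase-resampled to 500 Hz, re-referenced to the
standard longitudinal ("double banana") bipolar montage over the 19
electrodes of the 10–20 system (18 derived channels; configurable, with
a consecutive-pair fallback for reduced-montage recordings), cut into
contiguous non-overlapping 2-s epochs ([kL, (k+1)L) sample intervals,
trailing partial epoch dropped), and screened for artifacts. Band-pass
filtering uses a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`) with reflective padding of at least three time constants
of the low edge — zero-phase filtering is mandatory because phase is the
measured quantity (verified by a zero-lag cross-correlation test). Six
bands: delta 1–4, theta 4–8, alpha 8–13, low beta 13–20, high beta
20–29, and combined beta 13–29 Hz. Filtering is per-epoch by default;
filter-then-epoch is available and equivalent for stationary signals.

Artifact screening is a programmatic stand-in for visual review, not a
claim of equivalence: an epoch is dropped when any channel exceeds
±200 µV peak amplitude or any channel's range falls below 0.1 µV
(flatline). Rejections are logged; an empty result raises an
insufficient-clean-data error.

## Synthetic cohorts

Each subject's EEG is a set of narrowband oscillators sharing a common
carrier phase Φ(t) (phase of band-limited Gaussian noise), with channel
c carrying cos(Φ(t) + c·λ + θ_c(t)) at nominal amplitude 20 µV plus
white noise (`noise_sd`, relative to oscillation amplitude 1). The
per-channel jitter θ_c is an independent Langevin diffusion,

  dθ = −(κ/τ) sin θ dt + sqrt(2/τ) dW,   τ = 0.1 s,

whose stationary law is von Mises(0, κ). Coupling strength c ∈ [0, 1]
maps to concentration via κ = tan(c·π/2), capped at 200 (c = 1 is
special-cased to a rigid lock). Stationarity gives the closed-form pair
expectation PLV ≈ (I₁(κ)/I₀(κ))², and the diffusive dynamics make
uncoupled phases decorrelate within seconds, so independence genuinely
looks independent to the estimators. The diffusion is integrated by
Euler–Maruyama, sub-stepped so the drift per step stays below one half.
Optional volume conduction applies a real symmetric zero-lag mixing
matrix (1−m)·I + (m/n)·J. The jitter timescale τ = 0.1 s balances two
pressures: slower jitter leaves uncoupled channels phase-locked over
whole epochs; much faster jitter broadens the oscillation beyond its
band.

A cohort plants the responder label first (exactly
round(fraction·n) responders; default 37/70), then draws everything else
consistently: responders receive elevated high-beta coupling (defaults
0.50 vs 0.45 — calibrated once so the default pipeline's mean global
high-beta PLI *gap* between groups is ≈ 0.013, the published
responder/non-responder gap this generator emulates; absolute levels sit
near the per-epoch floor, not the published absolute means);
clinical covariates are drawn from pooled published distributions of a
70-child VNS cohort with *no* group difference by default (an additive
responder shift is available for power tests); and seizure diaries are
drawn so the reduction fraction matches the label, with responder
reductions mirroring the observed R100/R80 shares (27 % seizure-free,
76 % at ≥ 80 %). Age at implantation is onset age plus epilepsy duration
for internal consistency. All randomness flows from one integer seed
through a per-subject `SeedSequence` split: cohorts are bit-identical
across runs and individual subjects reproducible in isolation.

What the generator does **not** emulate: 1/f background spectra, ictal
or epileptiform activity, realistic head-volume conduction (a forward
model), non-stationarity across the recording, or the between-subject
heterogeneity of real cohorts (its between-subject feature SDs are much
smaller than published ones, so group tests on default cohorts are
better powered than the real study). Passing tests therefore certify
the estimators and the inference machinery, not clinical performance.

## Responder labeling and group statistics

Reduction = (baseline − followup)/baseline from the seizure diary;
tiers are inclusive: ≥ 1.0 → R100, ≥ 0.8 → R80, ≥ 0.5 → R50, else NR50
(negative reductions allowed). The binary analysis label is R50 vs NR50.

Continuous covariates: Mann–Whitney U, exact enumeration when the
pooled tie-free sample size is ≤ 12, otherwise the tie-corrected,
continuity-corrected normal approximation. Nominal covariates:
chi-square without continuity correction, switching to Fisher's exact
for 2×2 tables with any expected count < 5 (larger sparse tables keep
chi-square with a warning). Seizure types are non-exclusive, so their
2×k table is a descriptive tally. Normality screening uses a one-sample
KS test against a normal with the sample mean/SD — with the Lilliefors
caveat (parameters estimated from the same sample make it
conservative); it is descriptive only. Synchronization features:
Mann–Whitney per band with Benjamini–Hochberg FDR within each metric
across the five tested bands (combined beta is extracted as a model
feature but excluded from testing, so the FDR family size is 5); a
t-test mode exists behind a flag. α = 0.05, two-sided throughout; no
correction on the descriptive clinical table.

## Prediction model

25 encoded clinical columns (8 numeric, one-hot etiology ×4, multi-hot
seizure type ×4, one-hot syndrome ×4, one-hot MRI ×3, 2 ASM counts;
gender and benzodiazepine use are carried but not encoded) plus the 18
synchronization features form the 43-column integrated matrix;
clinical-only (25) and sync-only (18) modes support the ablation
comparison. Responder is the positive class.

The classifier is a linear SVM inside stratified nested CV: 10 outer
folds estimate generalization; 5 inner folds on each outer-training
split choose the cost C ∈ {0.01, 0.1, 1, 10, 100} and the number of
features kept ∈ {5, 10, 15, 20, 30, 43} by mean inner accuracy, ties
preferring fewer features then smaller C. Feature selection is either
the two-class Fisher F-score filter,
((x̄₊−x̄)² + (x̄₋−x̄)²) / (s₊² + s₋²) (constant features score 0; ties
break by column index; the default), or SVM-based recursive feature
elimination removing one smallest-|weight| feature per step.
Standardization (z-score, outer-training statistics only; indicator
columns scaled identically so weights stay comparable) precedes
selection and fitting — nothing outside the training split ever touches
the model, which the label-permutation test certifies (mean outer
accuracy 0.5 ± 0.1). Outer-fold predictions and decision scores are
pooled for the confusion matrix, accuracy, precision and a single
pooled-score ROC/AUC. The reported "coefficients" are the linear SVM
weights (in standardized space) of features selected in at least half
the outer folds, summarized as mean ± SD over the folds where selected —
this package's reading of feature-importance bars sometimes labeled
"principal components" in clinical ML reports; no PCA is performed.
External validation refits one pipeline (scale → select → fit, settings
chosen by inner CV) on all discovery subjects and applies it unchanged
to the held-out cohort.

## Numerical conventions

* Phase wrapping to (−π, π] via angle(e^{iΔφ}); sign(0) = 0.
* Hilbert edge trim: 10 % of samples per epoch end, configurable.
* Degenerate wPLI → 0 with a logged flag (relative threshold 10⁻¹²).
* wPLI symmetry is exact to 1 ulp (summation order), not bit-exact.
* Filter padding: min(3·fs/low_edge, segment length − 1) samples.
* EDF writing: 16-bit samples, 1-s records, physical range per channel
  from the data; round-trip error is bounded by range/65535. Sub-second
  tails are dropped (EDF stores whole records). Reading normalizes
  vendor label decorations ("EEG Fp1-Ref" → "Fp1").

## Problem sizes in tests

Monte-Carlo suites run on scaled-down recordings chosen as the package's
own trade-off between statistical resolution and turnaround: power and
null-calibration cohorts use n = 70 subjects, 3 channels, 8 s at 250 Hz,
100 replicates (planted high-beta coupling 0.8 vs 0.4 against a 0.45/0.45
null); the volume-conduction property uses 2 channels × 60 s × 20 seeds;
the no-leakage check permutes labels of one extracted 70-subject cohort
over 50 nested-CV runs with a reduced hyperparameter grid. Under these
conditions the planted effect is detected after FDR in ≈ 100 % of
replicates and the null familywise rate stays at the nominal ≈ 5 %.
The high-beta oscillator's spectral skirt reaches into the adjacent
low-beta band, so a planted high-beta effect can legitimately co-flag
low beta; well-separated bands (delta/theta/alpha) stay null.

## Known limitations

* The artifact screen catches amplitude/flatline artifacts only — no
  ocular regression or ICA; real eye-movement artifacts below ±200 µV
  pass.
* The per-epoch estimator floor means absolute metric levels are not
  comparable across epoch lengths or bands of different widths; only
  within-study contrasts are.
* Exact Mann–Whitney enumeration is skipped in the presence of ties.
* The generator's single-oscillator-per-band design cannot express
  band-specific coupling in more than one band per recording.
* EDF writing assumes an integer sampling rate.
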
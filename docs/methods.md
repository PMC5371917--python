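# Methods

This note documents the models, estimators and design choices behind the
package, in the spirit of a methods appendix: what is computed, under what
assumptions, with which defaults, and what the synthetic experiments do and
do not demonstrate.

## Signal model and windowing

Input is tri-axial acceleration (m/s², axes x/y/z) sampled uniformly at
`fs` (default 50 Hz, a common smartwatch rate). Real device logs carry
timestamp jitter; the reader accepts per-step deviations up to 20% of the
sample period (`|Δt − 1/fs| ≤ 0.2/fs`), snaps accepted timestamps onto the
ideal grid, and rejects anything worse, naming the first offending row.
Recordings are segmented into fixed windows of `round(window_seconds·fs)`
samples (default 2 s → 100 samples), trailing remainder discarded; overlap
is available but defaults to 0 so that windows are statistically
independent. Class labels attach per recording, matching single-task
recording sessions.

Gravity appears as a ~9.81 m/s² offset on z. It is deliberately kept at
I/O time (amplitude features see the raw signal) and removed per window by
mean subtraction before every spectral computation, which kills the DC line
without touching the dynamics.

## Higher-order spectral estimators

**Bispectrum.** Direct Fourier-domain estimator: the series is cut into
`segment_len` segments (default 64 samples, 50% overlap, Hann taper, mean
removed per segment) and `X(f1)·X(f2)·X*(f1+f2)` is averaged across
segments; the magnitude over `f1, f2 ∈ [0, fs/2]` is returned. The direct
estimator is used because the quantity is defined in the Fourier domain;
segment averaging is what suppresses the bispectrum of Gaussian noise
(magnitude of an incoherent average decays like 1/√n_segments), so
Gaussian-suppression behavior only manifests on series long enough to hold
tens of segments. Scalar features are taken over the principal domain
(`f2 ≤ f1`, `f1 + f2 ≤ fs/2`), the non-redundant triangle from which the
full plane follows by symmetry.

**Wigner-Ville distribution.** Discrete pseudo-WVD of the analytic signal
(Hilbert transform removes negative frequencies, suppressing the
cross-terms a real signal would create between its positive- and
negative-frequency images): per time index, FFT over the lag-limited
instantaneous autocorrelation `z[n+m] z*[n−m]`, `|m| ≤ max_lag`. The lag
product doubles the phase advance of a tone, so the `nfft` bins span
`[0, fs/2)`. Two exact discrete properties anchor the tests: a noiseless
tone peaks at its own frequency in every interior frame, and summing a
frame over all bins returns `nfft·|z[n]|²` (all non-zero lags cancel in the
DFT column sum).

**Wigner bispectrum and trispectrum.** The order-k time-varying spectra
involve lag shifts of `1/(k+1)` and `k/(k+1)` of each lag variable.
Nearest-neighbour rounding of those fractional shifts destroys the swap
symmetry of the (f1, f2) plane, so the signal is instead oversampled ×3
(bispectrum, k=2) or ×4 (trispectrum, k=3) by FFT-based band-limited
interpolation, after which every shift is an integer index on the fine
grid — exact for band-limited signals. The k=2 kernel over integer lags
(u, v) in original-sample units is

    K[u, v] = y*(t − u − v) · y(t + 2u − v) · y(t + 2v − u)

with a 2-D DFT over (u, v); the k=3 spectrum is evaluated on its diagonal
slice only (all three lags equal), collapsing the kernel to
`y*(t − 3u) · y(t + u)³` and a 1-D DFT. The full 4-D trispectrum is never
materialized: on 100-sample windows it would be both enormous and unused,
since only scalar summaries feed the classifier. Time frames are evaluated
every 4th original sample by default (`time_decimation`) to bound cost;
amplitude scaling is cubic for the third-order spectra and quartic for the
trispectrum diagonal, which the tests verify.

Every FFT path has a direct-summation twin in the test suite (explicit DFT
sums, nested lag loops, no FFT); agreement to < 1e-9 relative error on
random signals is the core correctness argument.

## The feature battery

34 features per axis, 102 per window, frozen in
`src/wearsense/feature_manifest.csv` (name, group, axis, ordinal, units):

| group | count | content |
|---|---|---|
| time | 5 | max, min, peak-to-peak, variance, 16-bin amplitude-histogram entropy |
| fft | 6 | dominant frequency and magnitude, spectral centroid, spectral entropy, band-energy fractions 0–3 and 3–12 Hz |
| dct | 5 | magnitudes of DCT-II coefficients 1–4, energy fraction of the first 10 coefficients |
| zt | 4 | z-transform magnitude at radius 0.95, angles π/8, π/4, π/2, 3π/4 |
| bispec | 6 | max, mean, principal-domain sum, entropies of normalized magnitude and squared magnitude, f1 of the argmax |
| wb | 5 | global max, mean, entropy, time-averaged diagonal max, diagonal-peak frequency |
| wt | 3 | diagonal max, mean, entropy |

Conventions: entropies in bits with `0·log 0 ≡ 0` and degenerate
distributions mapping to 0; per-axis mean removal before the histogram and
all spectral families (so a constant offset moves only max and min); the
z-transform is evaluated *off* the unit circle (radius 0.95) because on it
the z-transform coincides with the DTFT already covered by the FFT group.
HOS parameters are frozen at `max_lag = 24`, `nfft = 64`,
`time_decimation = 4`, `segment_len = 64`; for windows shorter than the
defaults support, `max_lag` is clamped to keep the lag kernel inside the
window. No feature is ever NaN on finite input — an all-zero window maps
to 102 zeros.

The battery is an explicit, versioned registry: the feature *families* are
standard for this problem, but their exact composition is this package's
canonical choice, and persisted models refuse to load under a mismatched
manifest version.

## Synthetic motion generator

The generator stands in for undeposited human recordings, emulating the
gross wrist-sensor signatures of each behavior:

* **flapping** — sinusoid at `base_freq` (default 3 Hz, a typical flapping
  rate) with a weak 2nd harmonic (5% of amplitude) and slow amplitude
  modulation (0.3 Hz, 4% depth), dominant on x with a smaller z component;
  default amplitude 8 m/s² (vigorous motion). The modulation/harmonic
  fractions are small enough that the noiseless peak-to-peak on the
  dominant axis stays within [1.8·A, 2.2·A].
* **painting** — low-passed (< ~1 Hz) random-walk drift normalized to
  0.7·amplitude RMS plus a 4–6 Hz tremor at 25% of amplitude; default
  amplitude 2 m/s². The drift is normalized by RMS (not peak) so its
  spectral power genuinely dominates the tremor and sensor noise; this is
  what keeps painting's spectral centroid below flapping's at the default
  noise level.
* **sibbing** — Poisson train (default 1.5 events/s) of exponentially
  decaying spikes (τ = 60 ms) on z with ±30% per-event amplitude
  variation, default amplitude 10 m/s², over a quiet baseline.

All classes add gravity on z and white Gaussian noise (default
`noise_sd = 0.3` m/s²). Per-subject variation multiplies frequency and
amplitude by a fixed uniform ±15% factor per synthetic subject (default 14
subjects, round-robin assignment). Each recording draws from an RNG stream
derived from `(seed, counter)`, so datasets are bit-identical for a fixed
seed and earlier recordings never change when more are requested.

The default study is 55 recordings per class of one 2-s window each —
165 balanced samples. One window per recording was chosen over cutting
many windows from longer recordings so that cross-validation folds never
contain windows from the same recording on both sides of the split.

**What the generator does not model:** orientation drift of the watch,
gravity rotation during movement, biomechanical coupling between axes,
non-stationary behavior onset/offset within a window, or the
inter-session variability of real participants. Consequently, the perfect
accuracy on the default synthetic study demonstrates that the pipeline
separates classes whose spectral and impulsive signatures differ — it is
not a claim about accuracy on real wrist-sensor data. The harder
conditions (noise_sd up to 3 m/s²) exercised in the robustness tests show
graceful, monotone degradation.

## Classifier and evaluation

`BaggedTreesClassifier` implements classical bootstrap aggregating: each
of 40 unpruned Gini CART trees (scikit-learn `DecisionTreeClassifier`)
trains on a with-replacement resample of the training set of equal size;
prediction is by majority vote with ties broken toward the first class in
the fixed order (flapping, painting, sibbing). Majority voting — rather
than probability averaging — is implemented directly because the vote
fractions are the scores the ROC analysis consumes.

Evaluation is stratified 10-fold cross-validation repeated 10 times with
reshuffled folds; stratification keeps the balanced design balanced within
folds. The confusion matrix pools all folds and repeats (each sample
predicted exactly once per repeat), so the reported overall accuracy
equals both `trace/sum` of the pooled matrix and the mean of per-repeat
accuracies, an identity checked to 1e-12. ROC analysis is one-vs-rest per
class on the pooled vote fractions, macro-averaged; the AUC computation is
cross-checked in tests against the exhaustive pairwise rank statistic.

The comparison harness runs six classifiers on *identical* fold
assignments (verified by hashing the fold indices): a complex tree
(≤ 100 splits), simple tree (≤ 4 splits), linear and Gaussian-kernel SVMs
(margin scores mapped through a softmax for ROC), AdaBoost with 30
learners, and the 40-tree bagged ensemble. Split budgets live in
`COMPARISON_CONFIG`, not hard-coded at call sites. Wall-clock training
time is reported for orientation only — it is hardware-dependent and
excluded from all assertions, and the pipeline's determinism contract
(byte-identical reports for identical configs) is preserved by omitting
the timing column from the pipeline's comparison CSV.

## Numerical and degenerate-input choices

* Jitter tolerance 0.2/fs; beyond it a file is rejected rather than
  resampled — silent resampling would hide sensor faults.
* Entropy of an empty/degenerate distribution is 0 by convention, making
  constant windows valid inputs everywhere.
* `max_lag` clamping for short windows keeps every lag index in bounds;
  the spectra requirements (`n ≥ 3·max_lag` for the Wigner bispectrum,
  `n ≥ 4·max_lag` for the trispectrum diagonal) are enforced with the
  minimum length named in the error.
* Bispectrum peak-localization tests use `nfft = 128` on 64-sample
  segments: zero-padding refines the frequency grid so the argmax bin is
  the grid point nearest the true coupling pair; at `nfft = 64` the
  coarse grid biases the argmax toward the bin whose sum index falls
  nearest the third tone.
* Vote ties are broken deterministically by class order; fold shuffling,
  bootstrap resampling and tree seeds all derive from the user seed.

## Problem sizes

Default analyses run on the 165-sample study (165 windows × 102 features;
10×10-fold CV of 40 trees ≈ 4000 tree fits). The direct-summation oracle
comparisons use short signals (N ≤ 64, `max_lag ≤ 8`) because the
brute-force references are quartic-to-quintic in their parameters; at
those sizes FFT and direct summation agree to near machine precision,
which transfers to all sizes since the FFT path is size-agnostic.
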
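# wearsense

Detection of stereotypical motor movements (SMMs) — hand flapping, painting,
and "sibbing" (self-directed head hitting) — from wrist-worn tri-axial
accelerometer data, for researchers and engineers working on wearable
monitoring of autism-related behaviors.

The pipeline windows 50 Hz acceleration recordings into 2-s segments,
computes a 102-element feature battery (34 features per axis), and
classifies windows with a bagged ensemble of 40 decision trees evaluated by
repeated stratified 10-fold cross-validation. The distinguishing ingredient
of the battery is a set of higher-order spectral (HOS) features:

* **Bispectrum** — the third-order spectrum
  `B(f1, f2) = E[X(f1) X(f2) X*(f1 + f2)]`, estimated by segment-averaged
  triple products of the FFT. It is blind to Gaussian noise and lights up
  under quadratic phase coupling, a signature of nonlinear, repetitive
  motion.
* **Wigner-Ville distribution (WVD)** — the bilinear time-frequency map
  `W(t, f) = Σ_τ z(t+τ) z*(t-τ) e^(-j4πfτ)` of the analytic signal,
  resolving when spectral content occurs.
* **Wigner bispectrum / trispectrum** — time-varying third- and
  fourth-order spectra combining both ideas; lag shifts of 1/3 and 1/4 of a
  sample are realized exactly by band-limited oversampling. Every
  FFT-accelerated estimator is tested to < 1e-9 relative error against a
  literal direct-summation implementation.

Because no recordings from the original wrist-sensor study are publicly
available, the package ships a synthetic motion generator with one model
per behavior class (quasi-periodic oscillation, drift-plus-tremor, sparse
impacts), per-subject parameter jitter, and controllable sensor noise; all
analyses are reproducible end to end from a seed.

## Worked example

```python
import numpy as np
from wearsense import (generate_dataset, segment_windows, feature_matrix,
                       repeated_kfold_cv)

recs = generate_dataset(n_per_class=55, duration=2.0, seed=7)   # 165 recordings
windows = [w for r in recs for w in segment_windows(r)]         # 2-s windows
X, labels = feature_matrix(windows)
print("feature matrix:", X.shape)

report = repeated_kfold_cv(X, np.asarray(labels), K=10, n_repeats=10,
                           n_trees=40, seed=7)
print(f"overall accuracy: {report.overall_accuracy:.4f}")
print(f"macro one-vs-rest AUC: {report.auc:.4f}")
print(report.confusion)
```

prints

```
feature matrix: (165, 102)
overall accuracy: 1.0000
macro one-vs-rest AUC: 1.0000
[[550   0   0]
 [  0 550   0]
 [  0   0 550]]
```

Each of the 165 balanced windows (55 per class) is described by 102
features; the pooled confusion matrix counts each window once per repeat
(10 repeats × 55 = 550 per row), and at the default sensor-noise level
(0.3 m/s²) the three synthetic behaviors are fully separable. Raising
`noise_sd` in `generate_dataset` degrades accuracy monotonically, which is
the regime used in the robustness tests.

The same pipeline is available from the shell:

```sh
wearsense synth --n-per-class 55 --duration 2 --seed 7 --out data/
wearsense run --input-manifest data/manifest.csv --out results/
wearsense compare --input-manifest data/manifest.csv --out results/
```

`run` writes the confusion matrix, classifier-comparison table, ROC points,
feature matrix and the effective config; re-running the same config yields
byte-identical reports.

Estimators compose with scikit-learn: `WindowFeaturizer` (windows → 102
features) and `BaggedTreesClassifier` (bootstrap bags + majority vote,
ties to the first class in order) work inside `sklearn.pipeline.Pipeline`.

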
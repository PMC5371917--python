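"""The 102-element feature battery: 34 features per accelerometer axis.

Per axis the battery spans seven families — time-domain amplitude
statistics, FFT spectral shape, DCT coefficients, off-unit-circle
z-transform probes, and scalar summaries of the bispectrum, Wigner
bispectrum and Wigner trispectrum diagonal. The exact registry (names,
groups, order) is frozen in ``feature_manifest.csv`` shipped with the
package so that trained models remain interpretable and reproducible.

Conventions
-----------
* Entropies are Shannon entropies in bits; ``0 * log 0 == 0`` and any
  degenerate (single-support or all-zero) distribution has entropy 0.
* The per-axis series is mean-removed before every spectral family and
  before the amplitude histogram, so adding a constant to a window changes
  only ``max`` and ``min``. TIME features use raw values.
* No feature is ever NaN or infinite for finite input, including constant
  and all-zero windows (where every feature is 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft, rfftfreq
from sklearn.base import BaseEstimator, TransformerMixin

from . import hos
from .exceptions import ParameterError
from .io_accel import Window

AXES = ("x", "y", "z")

#: Registry version embedded in persisted models; bump on any change to the
#: feature list, its order, or the frozen HOS parameters below.
MANIFEST_VERSION = "1.0"

#: HOS parameters frozen for feature extraction.
HOS_DEFAULTS = dict(max_lag=24, nfft=64, time_decimation=4, segment_len=64)

_HIST_BINS = 16

# (name, units) per group; order here IS the canonical within-axis order.
_REGISTRY_GROUPS = [
    ("time", [("max", "m/s^2"), ("min", "m/s^2"), ("ptp", "m/s^2"),
              ("variance", "(m/s^2)^2"), ("hist_entropy", "bit")]),
    ("fft", [("dom_freq", "Hz"), ("dom_mag", "m/s^2"), ("centroid", "Hz"),
             ("spec_entropy", "bit"), ("band_0_3", "1"), ("band_3_12", "1")]),
    ("dct", [("c1", "m/s^2"), ("c2", "m/s^2"), ("c3", "m/s^2"), ("c4", "m/s^2"),
             ("first10_energy", "1")]),
    ("zt", [("r095_pi8", "m/s^2"), ("r095_pi4", "m/s^2"),
            ("r095_pi2", "m/s^2"), ("r095_3pi4", "m/s^2")]),
    ("bispec", [("max", "(m/s^2)^3"), ("mean", "(m/s^2)^3"), ("sum_pd", "(m/s^2)^3"),
                ("entropy_p1", "bit"), ("entropy_p2", "bit"), ("argmax_f1", "Hz")]),
    ("wb", [("max", "(m/s^2)^3"), ("mean", "(m/s^2)^3"), ("entropy", "bit"),
            ("diag_max_tavg", "(m/s^2)^3"), ("diag_peak_freq", "Hz")]),
    ("wt", [("diag_max", "(m/s^2)^4"), ("diag_mean", "(m/s^2)^4"),
            ("diag_entropy", "bit")]),
]

_ZT_RADIUS = 0.95
_ZT_ANGLES = (np.pi / 8, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def feature_names(axes: Sequence[str] = AXES) -> list[str]:
    """The 102 canonical feature names, axis blocks ordered x, y, z."""
    names = []
    for axis in axes:
        for group, feats in _REGISTRY_GROUPS:
            for fname, _ in feats:
                names.append(f"{axis}_{group}_{fname}")
    return names


FEATURE_NAMES = feature_names()
N_FEATURES_PER_AXIS = len(FEATURE_NAMES) // 3
N_FEATURES = len(FEATURE_NAMES)


def manifest_frame() -> pd.DataFrame:
    """The registry as a table (name, group, axis, ordinal, units)."""
    rows = []
    ordinal = 0
    for axis in AXES:
        for group, feats in _REGISTRY_GROUPS:
            for fname, units in feats:
                rows.append({"name": f"{axis}_{group}_{fname}", "group": group,
                             "axis": axis, "ordinal": ordinal, "units": units})
                ordinal += 1
    return pd.DataFrame(rows)


def load_manifest() -> pd.DataFrame:
    """The manifest as shipped with the installed package."""
    with resources.as_file(resources.files("wearsense") / "feature_manifest.csv") as p:
        return pd.read_csv(p)


@dataclass
class FeatureVector:
    """Ordered 102-element feature vector for one window."""

    values: np.ndarray
    names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    label: Optional[str] = None
    window_ref: Optional[tuple] = None  # (subject_id, start_index)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ParameterError(
                f"{len(self.values)} values for {len(self.names)} names"
            )


def _entropy_bits(weights: np.ndarray) -> float:
    """Shannon entropy in bits of non-negative weights; degenerate -> 0."""
    w = np.asarray(weights, dtype=float).ravel()
    total = w.sum()
    if total <= 0:
        return 0.0
    p = w[w > 0] / total
    return float(-(p * np.log2(p)).sum())


def _time_features(s: np.ndarray) -> list[float]:
    smax = float(np.max(s))
    smin = float(np.min(s))
    var = float(np.var(s))
    centered = s - s.mean()
    if np.ptp(centered) > 0:
        counts, _ = np.histogram(centered, bins=_HIST_BINS)
        hist_ent = _entropy_bits(counts)
    else:
        hist_ent = 0.0
    return [smax, smin, smax - smin, var, hist_ent]


def _fft_features(s0: np.ndarray, fs: float) -> list[float]:
    mag = np.abs(rfft(s0))
    freqs = rfftfreq(len(s0), d=1.0 / fs)
    power = mag**2
    total = power.sum()
    k = int(np.argmax(mag))
    dom_freq = float(freqs[k])
    dom_mag = float(mag[k]) * 2.0 / len(s0)  # amplitude-normalized
    if total > 0:
        centroid = float((freqs * power).sum() / total)
        spec_ent = _entropy_bits(power)
        band03 = float(power[freqs <= 3.0].sum() / total)
        band312 = float(power[(freqs > 3.0) & (freqs <= 12.0)].sum() / total)
    else:
        centroid = spec_ent = band03 = band312 = 0.0
    return [dom_freq, dom_mag, centroid, spec_ent, band03, band312]


def _dct_features(s0: np.ndarray) -> list[float]:
    c = dct(s0, type=2, norm="ortho")
    coeffs = [float(abs(c[i])) if i < len(c) else 0.0 for i in (1, 2, 3, 4)]
    energy = float((c**2).sum())
    first10 = float((c[:10] ** 2).sum() / energy) if energy > 0 else 0.0
    return coeffs + [first10]


def _zt_features(s0: np.ndarray) -> list[float]:
    # X(z) evaluated inside the unit circle; distinct from the DTFT probes.
    n = np.arange(len(s0))
    out = []
    for theta in _ZT_ANGLES:
        z = _ZT_RADIUS * np.exp(1j * theta)
        out.append(float(np.abs(np.sum(s0 * z ** (-n)))) / len(s0))
    return out


def _bispec_features(s0: np.ndarray, fs: float, nfft: int, segment_len: int) -> list[float]:
    g = hos.bispectrum(s0, nfft=nfft, segment_len=min(segment_len, len(s0)), fs=fs)
    vals = g.values
    mask = hos.principal_domain_mask(vals.shape[0])
    pd_vals = vals[mask]
    if vals.max() > 0:
        i, _ = np.unravel_index(int(np.argmax(np.where(mask, vals, -1.0))), vals.shape)
        argmax_f1 = float(g.f_axis[i])
    else:
        argmax_f1 = 0.0
    return [
        float(vals.max()),
        float(vals.mean()),
        float(pd_vals.sum()),
        _entropy_bits(pd_vals),
        _entropy_bits(pd_vals**2),
        argmax_f1,
    ]


def _wb_features(s0: np.ndarray, fs: float, max_lag: int, decim: int) -> list[float]:
    max_lag = min(max_lag, (len(s0) - 1) // 3)
    g = hos.wigner_bispectrum(s0, fs=fs, max_lag=max_lag, time_decimation=decim)
    vals = g.values  # (t, f1, f2)
    diag = vals[:, np.arange(vals.shape[1]), np.arange(vals.shape[2])]
    diag_tavg = diag.mean(axis=0)
    peak_freq = float(abs(g.f_axis[int(np.argmax(diag_tavg))])) if diag_tavg.max() > 0 else 0.0
    return [
        float(vals.max()),
        float(vals.mean()),
        _entropy_bits(vals),
        float(diag.max(axis=1).mean()),
        peak_freq,
    ]


def _wt_features(s0: np.ndarray, fs: float, max_lag: int, decim: int) -> list[float]:
    max_lag = min(max_lag, (len(s0) - 1) // 4)
    g = hos.wigner_trispectrum_diag(s0, fs=fs, max_lag=max_lag, time_decimation=decim)
    vals = g.values
    return [float(vals.max()), float(vals.mean()), _entropy_bits(vals)]


def extract_axis_features(s, fs: float, hos_params: Optional[dict] = None) -> np.ndarray:
    """Compute the 34 per-axis features of a single-axis window series.

    ``hos_params`` overrides the frozen defaults (max_lag, nfft,
    time_decimation, segment_len); the manifest records the defaults.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 1:
        raise ParameterError(f"expected 1-D axis series, got shape {s.shape}")
    if len(s) < 8:
        raise ParameterError(f"axis series too short ({len(s)} < 8 samples)")
    if not np.all(np.isfinite(s)):
        raise ParameterError("axis series contains non-finite values")
    p = dict(HOS_DEFAULTS)
    if hos_params:
        p.update(hos_params)
    s0 = s - s.mean()  # spectra see the dynamic component only
    out = (
        _time_features(s)
        + _fft_features(s0, fs)
        + _dct_features(s0)
        + _zt_features(s0)
        + _bispec_features(s0, fs, p["nfft"], p["segment_len"])
        + _wb_features(s0, fs, p["max_lag"], p["time_decimation"])
        + _wt_features(s0, fs, p["max_lag"], p["time_decimation"])
    )
    arr = np.asarray(out, dtype=float)
    if len(arr) != N_FEATURES_PER_AXIS:
        raise ParameterError(f"internal registry mismatch: {len(arr)} features")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("non-finite feature value produced")
    return arr


def extract_features(w: Window, hos_params: Optional[dict] = None) -> FeatureVector:
    """Full 102-element feature vector of a window (axis blocks x, y, z)."""
    blocks = []
    for axis in AXES:
        try:
            blocks.append(extract_axis_features(w.axis(axis), w.fs, hos_params))
        except ParameterError as e:
            raise ParameterError(f"axis {axis!r}: {e}") from e
    return FeatureVector(
        values=np.concatenate(blocks),
        label=w.label,
        window_ref=(w.subject_id, w.start_index),
    )


def feature_matrix(windows: Sequence[Window], hos_params: Optional[dict] = None):
    """Stack windows into an (n_windows, 102) matrix plus a label list.

    Row order follows input order; column order is the registry.
    """
    if len(windows) == 0:
        raise ParameterError("empty window list")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ParameterError(f"mixed window lengths {sorted(lengths)}")
    X = np.empty((len(windows), N_FEATURES))
    labels = []
    for i, w in enumerate(windows):
        fv = extract_features(w, hos_params)
        X[i] = fv.values
        labels.append(w.label)
    return X, labels


class WindowFeaturizer(BaseEstimator, TransformerMixin):
    """sklearn transformer mapping windows to the 102-feature matrix.

    Stateless (``fit`` records nothing but enables pipeline composition).
    Accepts a list of :class:`~wearsense.io_accel.Window` or a raw
    (n_windows, n_samples, 3) array with ``fs`` taken from ``self.fs``.
    """

    def __init__(self, fs: float = 50.0, max_lag: int = 24, nfft: int = 64,
                 time_decimation: int = 4, segment_len: int = 64):
        self.fs = fs
        self.max_lag = max_lag
        self.nfft = nfft
        self.time_decimation = time_decimation
        self.segment_len = segment_len

    def _hos_params(self) -> dict:
        return dict(max_lag=self.max_lag, nfft=self.nfft,
                    time_decimation=self.time_decimation,
                    segment_len=self.segment_len)

    def fit(self, X, y=None):
        self.n_features_in_ = None
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        windows = self._as_windows(X)
        M, _ = feature_matrix(windows, self._hos_params())
        return M

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)

    def _as_windows(self, X) -> list[Window]:
        if len(X) and isinstance(X[0], Window):
            return list(X)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ParameterError(
                f"expected Window list or (n, samples, 3) array, got shape {arr.shape}"
            )
        return [Window(samples=a, fs=self.fs) for a in arr]
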
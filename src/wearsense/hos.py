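"""Higher-order spectra: bispectrum, Wigner-Ville distribution, and
Wigner higher-order spectra (bispectrum and trispectrum).

The power spectrum discards phase; third- and fourth-order spectra retain
phase relations between frequency triples/quadruples and therefore detect
quadratic/cubic phase coupling and deviations from Gaussianity. The
Wigner-Ville variants additionally resolve time, which suits the
non-stationary bursts a wrist accelerometer records.

Discretization of the Wigner higher-order spectra: the order-k definition
involves lag shifts of 1/(k+1) and k/(k+1) of each lag variable. Those
fractional shifts are realized exactly for band-limited signals by
oversampling the input by (k+1) with FFT-based band-limited interpolation,
after which every shift lands on an integer index of the fine grid. The
alternative (nearest-neighbour rounding) destroys the swap symmetries the
spectra are supposed to have.

Every FFT-accelerated path in this module has a same-definition
direct-summation counterpart in the test suite that it must match to
near machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as _signal
from scipy.fft import fft, fft2, rfft

from .exceptions import ParameterError

__all__ = [
    "SpectrumGrid",
    "bispectrum",
    "wvd",
    "wigner_bispectrum",
    "wigner_trispectrum_diag",
]


@dataclass
class SpectrumGrid:
    """A discretized spectrum magnitude with axis metadata.

    ``values`` is 2-D (f1 x f2) for the stationary bispectrum, 2-D (t x f)
    for the WVD and the trispectrum diagonal slice, and 3-D (t x f1 x f2)
    for the Wigner bispectrum. ``order`` is 2 for third-order spectra
    (bispectrum, WB) and 3 for the trispectrum.
    """

    values: np.ndarray
    f_axis: np.ndarray
    t_axis: Optional[np.ndarray] = None
    order: int = 2
    max_lag: Optional[int] = None
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.f_axis = np.asarray(self.f_axis, dtype=float)


def _as_1d_real(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError(f"expected a 1-D series, got shape {x.shape}")
    return x


def bispectrum(
    x,
    nfft: int = 64,
    segment_len: int = 64,
    fs: float = 50.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> SpectrumGrid:
    """Direct (Fourier-domain) bispectrum estimate of a real series.

    The series is cut into ``segment_len``-sample segments (``overlap``
    fractional overlap), each segment is mean-removed and tapered, and the
    triple product ``X(f1) X(f2) X*(f1 + f2)`` is averaged over segments.
    The returned grid covers f1, f2 in [0, fs/2] and is exactly symmetric
    under (f1, f2) swap; ``X*(f1 + f2)`` is taken from the full-length FFT
    so aliasing of the sum frequency is handled by the transform itself.
    """
    x = _as_1d_real(x)
    if segment_len < 8:
        raise ParameterError(f"segment_len must be >= 8, got {segment_len}")
    if len(x) < segment_len:
        raise ParameterError(
            f"series of {len(x)} samples shorter than one segment ({segment_len})"
        )
    if nfft < segment_len:
        raise ParameterError("nfft must be >= segment_len")

    step = max(1, int(round(segment_len * (1.0 - overlap))))
    taper = _signal.get_window(window, segment_len) if window else np.ones(segment_len)
    half = nfft // 2
    k = np.arange(half + 1)
    ksum = k[:, None] + k[None, :]  # f1 + f2 index, <= nfft, within full FFT range

    acc = np.zeros((half + 1, half + 1), dtype=complex)
    n_seg = 0
    for start in range(0, len(x) - segment_len + 1, step):
        seg = x[start : start + segment_len]
        seg = (seg - seg.mean()) * taper
        X = fft(seg, n=nfft)
        Xs = np.concatenate([X, X[:1]])  # index nfft == index 0 (periodicity)
        acc += X[k][:, None] * X[k][None, :] * np.conj(Xs[ksum])
        n_seg += 1
    B = np.abs(acc) / n_seg
    f_axis = np.arange(half + 1) * fs / nfft
    return SpectrumGrid(values=B, f_axis=f_axis, order=2, kind="bispectrum")


def principal_domain_mask(n_bins: int) -> np.ndarray:
    """Boolean mask of the non-redundant triangle f2 <= f1, f1 + f2 <= fs/2
    on an (n_bins x n_bins) half-spectrum grid (bin n_bins-1 = Nyquist)."""
    k = np.arange(n_bins)
    k1 = k[:, None]
    k2 = k[None, :]
    return (k2 <= k1) & (k1 + k2 <= n_bins - 1)


def wvd(x, fs: float = 50.0, max_lag: Optional[int] = None, nfft: Optional[int] = None) -> SpectrumGrid:
    """Discrete pseudo Wigner-Ville distribution of a real series.

    The analytic signal z (negative frequencies removed) suppresses the
    cross-terms a real signal would generate between its positive- and
    negative-frequency images. For each time index n the instantaneous
    autocorrelation ``z[n+m] z*[n-m]`` over lags ``|m| <= max_lag`` is
    Fourier-transformed; the real part is returned. Because the lag product
    advances the phase of a tone at f0 by 2 f0 per lag step, the frequency
    axis spans [0, fs/2) over the nfft bins.

    Summing a frame over all frequency bins gives ``nfft * |z[n]|^2``
    exactly (all non-zero lags cancel), the discrete time-marginal property.
    """
    x = _as_1d_real(x)
    n = len(x)
    if n < 8:
        raise ParameterError(f"series too short for WVD ({n} < 8 samples)")
    if max_lag is None:
        max_lag = n // 2 - 1
    max_lag = min(max_lag, n // 2 - 1)
    if nfft is None:
        nfft = 2 * max_lag + 1
    if nfft < 2 * max_lag + 1:
        raise ParameterError("nfft must be >= 2*max_lag + 1")

    z = _signal.hilbert(x)
    W = np.zeros((n, nfft))
    for t in range(n):
        L = min(max_lag, t, n - 1 - t)
        m = np.arange(-L, L + 1)
        kernel = np.zeros(nfft, dtype=complex)
        kernel[m % nfft] = z[t + m] * np.conj(z[t - m])
        W[t] = fft(kernel).real
    f_axis = np.arange(nfft) * fs / (2 * nfft)
    t_axis = np.arange(n) / fs
    return SpectrumGrid(values=W, f_axis=f_axis, t_axis=t_axis, order=1,
                        max_lag=max_lag, kind="wvd")


def _oversample(x: np.ndarray, factor: int) -> np.ndarray:
    """Band-limited (FFT) interpolation by an integer factor."""
    return _signal.resample(x, factor * len(x))


def _whos_frames(n_fine: int, margin: int, step_fine: int) -> np.ndarray:
    frames = np.arange(margin, n_fine - margin, step_fine)
    if len(frames) == 0:
        raise ParameterError("series too short for the requested max_lag")
    return frames


def wigner_bispectrum(
    x,
    fs: float = 50.0,
    max_lag: int = 24,
    time_decimation: int = 4,
) -> SpectrumGrid:
    """Wigner bispectrum (time-varying third-order spectrum) of a real series.

    For each retained time frame t the kernel over integer lags (p, q) in
    original-sample units is, on the 3x-oversampled signal y,

        K[p, q] = y*(t - p - q) . y(t + 2p - q) . y(t + 2q - p)

    (all shifts in fine-grid samples, exact thanks to oversampling), and the
    2-D DFT over (p, q) gives the (f1, f2) plane. Magnitude is returned:
    shape (n_frames, M, M) with M = 2*max_lag + 1. The grid is symmetric
    under (f1, f2) swap because the kernel is symmetric in (p, q).

    ``time_decimation`` evaluates every k-th original sample to bound cost.
    """
    x = _as_1d_real(x)
    n = len(x)
    if max_lag < 1:
        raise ParameterError("max_lag must be >= 1")
    if n < 3 * max_lag:
        raise ParameterError(
            f"series of {n} samples too short for max_lag={max_lag}; need >= {3 * max_lag}"
        )
    y = _oversample(x, 3)
    M = 2 * max_lag + 1
    # Lag tau = u original samples; on the 3x fine grid tau/3 is u fine samples,
    # so the three shifts -(u+v), 2u-v, 2v-u are integer fine-grid offsets.
    u = np.arange(-max_lag, max_lag + 1)[:, None]
    v = np.arange(-max_lag, max_lag + 1)[None, :]
    margin = 3 * max_lag  # largest |shift| in fine-grid samples
    frames = _whos_frames(len(y), margin, 3 * time_decimation)

    vals = np.empty((len(frames), M, M))
    for i, t in enumerate(frames):
        K = np.conj(y[t - u - v]) * y[t + 2 * u - v] * y[t + 2 * v - u]
        F = fft2(np.fft.ifftshift(K))
        vals[i] = np.abs(F)
    f_axis = np.fft.fftfreq(M, d=1.0 / fs)
    t_axis = frames / (3.0 * fs)
    return SpectrumGrid(values=vals, f_axis=f_axis, t_axis=t_axis, order=2,
                        max_lag=max_lag, kind="wigner_bispectrum")


def wigner_trispectrum_diag(
    x,
    fs: float = 50.0,
    max_lag: int = 24,
    time_decimation: int = 4,
) -> SpectrumGrid:
    """Diagonal slice (f1 = f2 = f3) of the Wigner trispectrum.

    Setting the three lag variables equal collapses the fourth-order kernel
    to a 1-D lag sequence on the 4x-oversampled signal y:

        K[p] = y*(t - 3p) . y(t + p)^3

    with p in fine-grid steps of one original sample; a 1-D DFT over p gives
    a (t x f) magnitude matrix. The full 4-D spectrum is never materialized:
    on 2-s windows the diagonal carries the scalar features downstream and
    keeps the cost linear in max_lag.
    """
    x = _as_1d_real(x)
    n = len(x)
    if max_lag < 1:
        raise ParameterError("max_lag must be >= 1")
    if n < 4 * max_lag:
        raise ParameterError(
            f"series of {n} samples too short for max_lag={max_lag}; need >= {4 * max_lag}"
        )
    y = _oversample(x, 4)
    M = 2 * max_lag + 1
    # Lag tau = u original samples; on the 4x fine grid tau/4 is u fine samples
    # and 3 tau/4 is 3u fine samples, both exact integer offsets.
    u = np.arange(-max_lag, max_lag + 1)
    margin = 3 * max_lag  # largest |shift| (3u) in fine-grid samples
    frames = _whos_frames(len(y), margin, 4 * time_decimation)

    vals = np.empty((len(frames), M))
    for i, t in enumerate(frames):
        K = np.conj(y[t - 3 * u]) * y[t + u] ** 3
        vals[i] = np.abs(fft(np.fft.ifftshift(K)))
    f_axis = np.fft.fftfreq(M, d=1.0 / fs)
    t_axis = frames / (4.0 * fs)
    return SpectrumGrid(values=vals, f_axis=f_axis, t_axis=t_axis, order=3,
                        max_lag=max_lag, kind="wigner_trispectrum_diag")
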
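"""Direct-summation reference implementations of the spectral estimators.

Each function evaluates the same discrete definition as its counterpart in
``wearsense.hos`` but by literal summation (explicit DFT sums, nested lag
loops) with no FFT, so agreement to ~1e-9 relative error validates the
FFT-accelerated path. Deliberately slow; use only at small N.
"""

import numpy as np
import scipy.signal as sp_signal


def dft(seg, nfft):
    """Explicit O(N^2) discrete Fourier transform."""
    n = np.arange(len(seg))
    return np.array([
        np.sum(seg * np.exp(-2j * np.pi * k * n / nfft)) for k in range(nfft)
    ])


def bispectrum_direct(x, nfft, segment_len, overlap=0.5, window="hann"):
    """Segment-averaged triple product X(k1) X(k2) X*(k1+k2), summed directly."""
    x = np.asarray(x, dtype=float)
    step = max(1, int(round(segment_len * (1.0 - overlap))))
    taper = sp_signal.get_window(window, segment_len) if window else np.ones(segment_len)
    half = nfft // 2
    acc = np.zeros((half + 1, half + 1), dtype=complex)
    n_seg = 0
    for start in range(0, len(x) - segment_len + 1, step):
        seg = x[start : start + segment_len]
        seg = (seg - seg.mean()) * taper
        X = dft(seg, nfft)
        for k1 in range(half + 1):
            for k2 in range(half + 1):
                ks = (k1 + k2) % nfft
                acc[k1, k2] += X[k1] * X[k2] * np.conj(X[ks])
        n_seg += 1
    return np.abs(acc) / n_seg


def wvd_direct(x, fs, max_lag=None, nfft=None):
    """Pseudo-WVD of the analytic signal by explicit lag/frequency loops."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag is None:
        max_lag = n // 2 - 1
    max_lag = min(max_lag, n // 2 - 1)
    if nfft is None:
        nfft = 2 * max_lag + 1
    z = sp_signal.hilbert(x)
    W = np.zeros((n, nfft))
    for t in range(n):
        L = min(max_lag, t, n - 1 - t)
        for k in range(nfft):
            s = 0.0 + 0.0j
            for m in range(-L, L + 1):
                s += z[t + m] * np.conj(z[t - m]) * np.exp(-2j * np.pi * k * m / nfft)
            W[t, k] = s.real
    return W


def wigner_bispectrum_direct(x, fs, max_lag, time_decimation=4):
    """Triple-product lag kernel on the 3x-oversampled signal, 2-D DFT by loops."""
    x = np.asarray(x, dtype=float)
    y = sp_signal.resample(x, 3 * len(x))
    L = max_lag
    M = 2 * L + 1
    frames = np.arange(3 * L, len(y) - 3 * L, 3 * time_decimation)
    out = np.empty((len(frames), M, M))
    for fi, t in enumerate(frames):
        for k1 in range(M):
            for k2 in range(M):
                s = 0.0 + 0.0j
                for uu in range(-L, L + 1):
                    for vv in range(-L, L + 1):
                        K = (np.conj(y[t - uu - vv])
                             * y[t + 2 * uu - vv]
                             * y[t + 2 * vv - uu])
                        s += K * np.exp(-2j * np.pi * (k1 * uu + k2 * vv) / M)
                out[fi, k1, k2] = abs(s)
    return out


def wigner_trispectrum_diag_direct(x, fs, max_lag, time_decimation=4):
    """Diagonal-slice fourth-order kernel on the 4x-oversampled signal."""
    x = np.asarray(x, dtype=float)
    y = sp_signal.resample(x, 4 * len(x))
    L = max_lag
    M = 2 * L + 1
    frames = np.arange(3 * L, len(y) - 3 * L, 4 * time_decimation)
    out = np.empty((len(frames), M))
    for fi, t in enumerate(frames):
        for k in range(M):
            s = 0.0 + 0.0j
            for uu in range(-L, L + 1):
                s += np.conj(y[t - 3 * uu]) * y[t + uu] ** 3 * np.exp(
                    -2j * np.pi * k * uu / M)
            out[fi, k] = abs(s)
    return out


def auc_pairwise(y_true_binary, scores):
    """AUC as the exhaustive positive-vs-negative comparison count
    (ties count 1/2) — the rank-statistic definition."""
    pos = [s for s, t in zip(scores, y_true_binary) if t]
    neg = [s for s, t in zip(scores, y_true_binary) if not t]
    if not pos or not neg:
        return float("nan")
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
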
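"""Reading, writing and windowing of tri-axial accelerometer recordings.

Recordings are CSV files with header ``timestamp,x,y,z``: timestamp in
seconds (float) or milliseconds (auto-detected when values exceed 1e6),
acceleration in m/s^2. Smartwatch logs jitter slightly around the nominal
sampling grid; timestamps within ``JITTER_TOLERANCE_FRACTION / fs`` of the
ideal step are snapped onto a uniform grid, anything worse is rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataQualityError, FormatError, ParameterError

logger = logging.getLogger(__name__)

#: Maximum tolerated deviation of successive timestamp differences from 1/fs,
#: expressed as a fraction of the sample period.
JITTER_TOLERANCE_FRACTION = 0.2

#: Labels of the three stereotypic-behavior classes, in canonical order.
CLASS_ORDER = ("flapping", "painting", "sibbing")

REQUIRED_COLUMNS = ("timestamp", "x", "y", "z")

#: Timestamps whose magnitude exceeds this are interpreted as milliseconds.
_MS_THRESHOLD = 1e6


@dataclass
class AccelRecording:
    """A uniformly sampled tri-axial acceleration series.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing on a uniform grid.
    ax, ay, az : ndarray
        Acceleration per axis in m/s^2, same length as ``t``.
    fs : float
        Sampling rate in Hz (smartwatch default: 50).
    label : str, optional
        Behavior class, one of ``CLASS_ORDER``.
    subject_id : str, optional
        Opaque subject identifier.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float = 50.0
    label: Optional[str] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        n = len(self.t)
        for name in ("ax", "ay", "az"):
            if len(getattr(self, name)) != n:
                raise ParameterError(
                    f"axis series {name!r} has length {len(getattr(self, name))}, "
                    f"expected {n} to match the time base"
                )
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise DataQualityError(f"timestamps not strictly increasing at sample {row + 1}")
            tol = JITTER_TOLERANCE_FRACTION / self.fs
            worst = np.max(np.abs(dt - 1.0 / self.fs))
            if worst > tol:
                raise DataQualityError(
                    f"timestamp jitter {worst:.6g}s exceeds tolerance {tol:.6g}s "
                    f"for fs={self.fs} Hz"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self) / self.fs

    @property
    def xyz(self) -> np.ndarray:
        """Samples as an (n, 3) array with axis order x, y, z."""
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass
class Window:
    """A fixed-length segment of a recording, ready for feature extraction."""

    samples: np.ndarray  # (n_samples, 3), axis order x, y, z
    fs: float
    label: Optional[str] = None
    subject_id: Optional[str] = None
    start_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ParameterError(
                f"window samples must have shape (n, 3), got {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise DataQualityError("window contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.shape[0]

    def axis(self, name: str) -> np.ndarray:
        """Single-axis series; ``name`` in {'x', 'y', 'z'}."""
        return self.samples[:, "xyz".index(name)]


def read_accel_csv(path, fs_expected: float = 50.0) -> AccelRecording:
    """Read a ``timestamp,x,y,z`` CSV into a validated :class:`AccelRecording`.

    Timestamps are regularized onto the uniform grid ``t[0] + k/fs`` once their
    jitter is confirmed to be below tolerance. Millisecond timestamps are
    auto-detected by magnitude and converted to seconds.

    Raises
    ------
    FormatError
        Missing column or empty file.
    DataQualityError
        Non-monotone timestamps or jitter above tolerance, naming the first
        offending row (1-based, counting the header as row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; header must be timestamp,x,y,z")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")

    t = df["timestamp"].to_numpy(dtype=float)
    if np.nanmax(np.abs(t)) > _MS_THRESHOLD:
        t = t / 1000.0
    if np.any(~np.isfinite(t)):
        row = int(np.argmax(~np.isfinite(t))) + 2
        raise DataQualityError(f"{path}: non-finite timestamp at row {row}")

    if len(t) > 1:
        dt = np.diff(t)
        bad = dt <= 0
        if np.any(bad):
            row = int(np.argmax(bad)) + 3  # +2 header/1-base, +1 diff offset
            raise DataQualityError(f"{path}: timestamps not strictly increasing at row {row}")
        tol = JITTER_TOLERANCE_FRACTION / fs_expected
        dev = np.abs(dt - 1.0 / fs_expected)
        if np.any(dev > tol):
            row = int(np.argmax(dev > tol)) + 3
            raise DataQualityError(
                f"{path}: timestamp jitter exceeds {tol:.6g}s at row {row} "
                f"(expected step {1.0 / fs_expected:.6g}s)"
            )
    # Snap to the ideal grid: jitter below tolerance is sensor clock noise.
    t_uniform = t[0] + np.arange(len(t)) / fs_expected
    return AccelRecording(
        t=t_uniform,
        ax=df["x"].to_numpy(dtype=float),
        ay=df["y"].to_numpy(dtype=float),
        az=df["z"].to_numpy(dtype=float),
        fs=fs_expected,
    )


def write_accel_csv(rec: AccelRecording, path) -> None:
    """Write a recording to CSV, parseable by :func:`read_accel_csv`.

    Values are written with enough digits (%.12g) to round-trip within float
    tolerance. An empty recording yields a header-only file.
    """
    path = Path(path)
    df = pd.DataFrame({"timestamp": rec.t, "x": rec.ax, "y": rec.ay, "z": rec.az})
    df.to_csv(path, index=False, float_format="%.12g")


def segment_windows(
    rec: AccelRecording,
    window_seconds: float = 2.0,
    overlap_fraction: float = 0.0,
) -> list[Window]:
    """Cut a recording into fixed-length windows.

    With window length ``w = round(window_seconds * fs)`` samples and step
    ``round(w * (1 - overlap_fraction))``, the number of windows is
    ``floor((N - w)/step) + 1``; the trailing partial window is discarded.
    A recording shorter than one window yields an empty list and a logged
    warning rather than an exception.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ParameterError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    w = int(round(window_seconds * rec.fs))
    if w < 4:
        raise ParameterError(f"window of {w} samples is too short (need >= 4)")
    step = max(1, int(round(w * (1.0 - overlap_fraction))))
    n = len(rec)
    if n < w:
        logger.warning(
            "recording %s: %d samples shorter than one %d-sample window; no windows produced",
            rec.subject_id or "<anon>", n, w,
        )
        return []
    xyz = rec.xyz
    windows = []
    for start in range(0, n - w + 1, step):
        windows.append(
            Window(
                samples=xyz[start : start + w],
                fs=rec.fs,
                label=rec.label,
                subject_id=rec.subject_id,
                start_index=start,
            )
        )
    return windows
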
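"""Synthetic tri-axial recordings of the three stereotypic behaviors.

The study's smartwatch recordings were never deposited, so this module
generates surrogate motion with the gross signatures a wrist sensor sees:

* ``flapping`` — sustained quasi-periodic oscillation: a sinusoid at
  ``base_freq`` (default 3 Hz) with a weak second harmonic, slowly
  amplitude-modulated, dominant on the x axis with a smaller z component.
* ``painting`` — low-amplitude irregular drift (low-passed random walk below
  ~1.5 Hz) plus a small 4-6 Hz tremor, spread over x/y.
* ``sibbing`` — sparse high-amplitude impacts: a Poisson train (default
  1.5 events/s) of exponentially decaying spikes on the z axis over a quiet
  baseline.

All classes carry the 9.81 m/s^2 gravity offset on z and additive white
Gaussian sensor noise. Everything is deterministic given the seed; the
dataset generator derives one independent stream per recording from a
counter, so generating more recordings never changes earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ParameterError
from .io_accel import CLASS_ORDER, AccelRecording, write_accel_csv

GRAVITY = 9.81  # m/s^2, static offset on z

# Motion-model constants. Modulation depth and harmonic fraction are kept
# small so the noiseless flapping peak-to-peak stays within ~[1.9A, 2.2A].
_FLAP_MOD_FREQ = 0.3      # Hz, slow amplitude modulation
_FLAP_MOD_DEPTH = 0.04
_FLAP_HARMONIC = 0.05     # fraction of amplitude at 2*base_freq
_PAINT_TREMOR_FRACTION = 0.25
_PAINT_DRIFT_CUTOFF = 1.0  # Hz low-pass for the drift component
_SIB_DECAY = 0.06          # s, impact decay time constant


@dataclass
class BehaviorParams:
    """Generative parameters for one behavior class.

    ``subject_jitter`` is the half-width of the uniform fractional
    perturbation applied per subject to ``base_freq`` and ``amplitude``
    (0.15 emulates inter-subject variation of ±15%).
    """

    class_name: str
    base_freq: float = 3.0       # Hz; event rate in events/s for sibbing
    amplitude: float = 1.0       # m/s^2
    noise_sd: float = 0.3        # m/s^2
    subject_jitter: float = 0.15
    seed: Optional[object] = None  # int or np.random.SeedSequence

    def validate(self, fs: float) -> None:
        if self.class_name not in CLASS_ORDER:
            raise ParameterError(
                f"unknown class {self.class_name!r}; expected one of {CLASS_ORDER}"
            )
        if self.base_freq >= fs / 2:
            raise ParameterError(
                f"base_freq {self.base_freq} Hz violates Nyquist for fs={fs} Hz"
            )
        if self.base_freq <= 0 or self.amplitude <= 0:
            raise ParameterError("base_freq and amplitude must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


#: Per-class defaults chosen so the default dataset is separable but not
#: trivially so at the default sensor-noise level.
DEFAULT_PARAMS = {
    "flapping": dict(base_freq=3.0, amplitude=8.0),
    "painting": dict(base_freq=0.8, amplitude=2.0),
    "sibbing": dict(base_freq=1.5, amplitude=10.0),
}


def default_params(class_name: str, noise_sd: float = 0.3, seed=None) -> BehaviorParams:
    """The package's canonical parameters for one behavior class."""
    if class_name not in DEFAULT_PARAMS:
        raise ParameterError(f"unknown class {class_name!r}")
    return BehaviorParams(class_name=class_name, noise_sd=noise_sd, seed=seed,
                          **DEFAULT_PARAMS[class_name])


def _flapping(rng, t, f0, amp):
    phase = rng.uniform(0, 2 * np.pi)
    mod = 1.0 + _FLAP_MOD_DEPTH * np.sin(2 * np.pi * _FLAP_MOD_FREQ * t + rng.uniform(0, 2 * np.pi))
    carrier = np.sin(2 * np.pi * f0 * t + phase)
    harmonic = _FLAP_HARMONIC * np.sin(2 * np.pi * 2 * f0 * t + rng.uniform(0, 2 * np.pi))
    x = amp * (mod * carrier + harmonic)
    z = 0.5 * amp * np.sin(2 * np.pi * f0 * t + phase + rng.uniform(-0.5, 0.5))
    y = 0.15 * amp * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    return x, y, z


def _painting(rng, t, f0, amp, fs):
    n = len(t)

    def drift():
        walk = np.cumsum(rng.standard_normal(n))
        if n > 12:  # low-pass the walk below ~1.5 Hz to model slow arm travel
            b, a = signal.butter(2, min(_PAINT_DRIFT_CUTOFF * (f0 / 0.8), 0.45 * fs) / (fs / 2))
            walk = signal.filtfilt(b, a, walk)
        walk = walk - walk.mean()
        rms = np.sqrt(np.mean(walk**2))
        return 0.7 * amp * walk / rms if rms > 0 else walk

    tremor_freq = rng.uniform(4.0, 6.0)
    tremor = _PAINT_TREMOR_FRACTION * amp * np.sin(
        2 * np.pi * tremor_freq * t + rng.uniform(0, 2 * np.pi)
    )
    x = drift() + tremor
    y = drift() + 0.5 * tremor
    z = 0.3 * drift()
    return x, y, z


def _sibbing(rng, t, rate, amp, fs):
    n = len(t)
    z = np.zeros(n)
    n_events = rng.poisson(rate * t[-1]) if n > 1 else 0
    starts = np.sort(rng.uniform(0, t[-1], size=n_events)) if n_events else []
    kernel_len = int(6 * _SIB_DECAY * fs)
    kernel_t = np.arange(kernel_len) / fs
    for s in starts:
        i = int(s * fs)
        a = amp * rng.uniform(0.7, 1.3)
        k = a * np.exp(-kernel_t / _SIB_DECAY)
        end = min(n, i + kernel_len)
        z[i:end] += k[: end - i]
    x = 0.15 * np.roll(z, 1)  # slight arm recoil on x
    y = np.zeros(n)
    return x, y, z


def simulate_behavior(params: BehaviorParams, duration: float, fs: float = 50.0) -> AccelRecording:
    """Simulate one recording of a single behavior.

    Deterministic given ``params.seed``. The z axis carries the gravity
    offset; all axes receive white Gaussian noise of sd ``params.noise_sd``.
    """
    params.validate(fs)
    n = int(round(duration * fs))
    if n < 4:
        raise ParameterError(f"duration {duration}s at {fs} Hz gives only {n} samples")
    rng = np.random.default_rng(params.seed)
    t = np.arange(n) / fs

    if params.class_name == "flapping":
        x, y, z = _flapping(rng, t, params.base_freq, params.amplitude)
    elif params.class_name == "painting":
        x, y, z = _painting(rng, t, params.base_freq, params.amplitude, fs)
    else:
        x, y, z = _sibbing(rng, t, params.base_freq, params.amplitude, fs)

    z = z + GRAVITY
    if params.noise_sd > 0:
        x = x + params.noise_sd * rng.standard_normal(n)
        y = y + params.noise_sd * rng.standard_normal(n)
        z = z + params.noise_sd * rng.standard_normal(n)
    return AccelRecording(t=t, ax=x, ay=y, az=z, fs=fs, label=params.class_name)


def generate_dataset(
    n_per_class: int = 55,
    duration: float = 2.0,
    fs: float = 50.0,
    n_subjects: int = 14,
    seed: int = 7,
    noise_sd: float = 0.3,
    classes: Sequence[str] = CLASS_ORDER,
) -> list[AccelRecording]:
    """Generate a balanced labelled dataset.

    Exactly ``n_per_class`` recordings per class, assigned round-robin to
    ``n_subjects`` synthetic subjects. Each subject perturbs frequency and
    amplitude by a fixed fraction (±15% by default), emulating individual
    variation across participants. One RNG stream per recording is derived
    from (seed, counter), so the output is bit-identical for a fixed seed
    regardless of how many recordings are requested later.
    """
    if n_per_class <= 0 or n_subjects <= 0:
        raise ParameterError("n_per_class and n_subjects must be positive")
    # Per-subject multiplicative jitter, from a stream disjoint from recordings.
    subj_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 999_983]))
    jitter = 0.15
    subj_mult = subj_rng.uniform(1 - jitter, 1 + jitter, size=(n_subjects, 2))

    recordings = []
    counter = 0
    for class_name in classes:
        base = default_params(class_name, noise_sd=noise_sd)
        for i in range(n_per_class):
            subject = counter % n_subjects
            fmult, amult = subj_mult[subject]
            params = BehaviorParams(
                class_name=class_name,
                base_freq=base.base_freq * fmult,
                amplitude=base.amplitude * amult,
                noise_sd=noise_sd,
                subject_jitter=jitter,
                seed=np.random.SeedSequence([int(seed), counter]),
            )
            rec = simulate_behavior(params, duration=duration, fs=fs)
            rec.subject_id = f"S{subject:02d}"
            recordings.append(rec)
            counter += 1
    return recordings


def write_dataset(recordings: Sequence[AccelRecording], out_dir) -> Path:
    """Write one CSV per recording plus a ``manifest.csv`` (filename, class, subject).

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(recordings):
        fname = f"rec_{i:04d}.csv"
        write_accel_csv(rec, out_dir / fname)
        rows.append({"filename": fname, "class": rec.label, "subject": rec.subject_id})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path, fs_expected: float = 50.0) -> list[AccelRecording]:
    """Load a dataset written by :func:`write_dataset` (or hand-built to match)."""
    from .io_accel import read_accel_csv

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    for col in ("filename", "class"):
        if col not in df.columns:
            raise ParameterError(f"manifest {manifest_path} missing column {col!r}")
    recs = []
    for _, row in df.iterrows():
        rec = read_accel_csv(manifest_path.parent / row["filename"], fs_expected=fs_expected)
        rec.label = row["class"]
        rec.subject_id = str(row.get("subject", "")) or None
        recs.append(rec)
    return recs
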
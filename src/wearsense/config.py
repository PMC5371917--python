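"""Run configuration: one flat, serializable record of every knob.

Defaults reproduce the reference settings: 50 Hz sampling, 2-s windows,
40-tree bagged ensemble, stratified 10-fold cross-validation averaged over
10 repeats. A run always writes its effective config next to its outputs
so any result can be replayed bit-for-bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

from .exceptions import ParameterError


@dataclass
class RunConfig:
    fs: float = 50.0
    window_seconds: float = 2.0
    overlap: float = 0.0
    max_lag: int = 24
    nfft: int = 64
    time_decimation: int = 4
    segment_len: int = 64
    n_trees: int = 40
    k_folds: int = 10
    n_repeats: int = 10
    seed: int = 7
    # synth-only knobs
    n_per_class: int = 55
    duration: float = 2.0
    n_subjects: int = 14
    noise_sd: float = 0.3
    # paths (None when driven purely in memory)
    input_manifest: Optional[str] = None
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if self.fs <= 0 or self.window_seconds <= 0:
            raise ParameterError("fs and window_seconds must be positive")
        if not 0 <= self.overlap < 1:
            raise ParameterError("overlap must be in [0, 1)")
        if min(self.n_trees, self.k_folds, self.n_repeats) < 1:
            raise ParameterError("n_trees, k_folds, n_repeats must be >= 1")

    def hos_params(self) -> dict:
        return dict(max_lag=self.max_lag, nfft=self.nfft,
                    time_decimation=self.time_decimation,
                    segment_len=self.segment_len)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def with_overrides(self, **kw) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in kw.items() if v is not None})
        cfg = RunConfig(**data)
        cfg.validate()
        return cfg
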
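"""End-to-end pipeline: recordings -> windows -> features -> CV reports.

Kept separate from the CLI so the same entry points drive scripts and
tests. Sample counts are logged at every stage boundary; counts are
conserved except where trailing partial windows are discarded.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classify, features, io_accel, synth
from .config import RunConfig
from .exceptions import ParameterError

logger = logging.getLogger(__name__)


def windows_from_recordings(recs: Sequence[io_accel.AccelRecording],
                            cfg: RunConfig) -> list[io_accel.Window]:
    windows: list[io_accel.Window] = []
    for rec in recs:
        windows.extend(io_accel.segment_windows(rec, cfg.window_seconds, cfg.overlap))
    logger.info("windowing: %d recordings -> %d windows", len(recs), len(windows))
    labels = {w.label for w in windows}
    if any(lab is None for lab in labels):
        raise ParameterError("unlabelled windows; every recording needs a class label")
    for cls in sorted(labels):
        if sum(w.label == cls for w in windows) == 0:
            raise ParameterError(f"class {cls!r} empty after windowing")
    return windows


def load_or_generate(cfg: RunConfig) -> list[io_accel.AccelRecording]:
    if cfg.input_manifest:
        recs = synth.read_dataset(cfg.input_manifest, fs_expected=cfg.fs)
        logger.info("loaded %d recordings from %s", len(recs), cfg.input_manifest)
    else:
        recs = synth.generate_dataset(
            n_per_class=cfg.n_per_class, duration=cfg.duration, fs=cfg.fs,
            n_subjects=cfg.n_subjects, seed=cfg.seed, noise_sd=cfg.noise_sd,
        )
        logger.info("generated %d synthetic recordings", len(recs))
    if not recs:
        raise ParameterError("no recordings found")
    return recs


def extract(cfg: RunConfig, recs=None):
    """Feature matrix + labels for a config (generating data if needed)."""
    recs = load_or_generate(cfg) if recs is None else recs
    windows = windows_from_recordings(recs, cfg)
    if not windows:
        raise ParameterError("no windows produced; recordings shorter than one window?")
    X, labels = features.feature_matrix(windows, cfg.hos_params())
    logger.info("features: %d windows -> matrix %s", len(windows), X.shape)
    return X, np.asarray(labels), windows


def run_pipeline(cfg: RunConfig, write_outputs: bool = True):
    """Full run: data -> features -> repeated-CV report (+ comparison table).

    When ``cfg.out_dir`` is set and ``write_outputs`` is true, writes
    ``confusion.csv``, ``comparison.csv``, ``roc.csv``, ``features.csv`` and
    the effective ``config.yaml``. The comparison CSV omits the wall-clock
    timing column so identical configs yield byte-identical reports.
    """
    cfg.validate()
    X, y, _ = extract(cfg)
    report = classify.repeated_kfold_cv(
        X, y, K=cfg.k_folds, n_repeats=cfg.n_repeats,
        n_trees=cfg.n_trees, seed=cfg.seed,
    )
    logger.info("CV: overall accuracy %.4f, macro AUC %.4f",
                report.overall_accuracy, report.auc)
    comparison = classify.compare_classifiers(X, y, K=cfg.k_folds, seed=cfg.seed)

    if write_outputs and cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        classify.confusion_to_frame(report).to_csv(out / "confusion.csv", index=False)
        comparison.drop(columns=["train_time_s"]).to_csv(
            out / "comparison.csv", index=False, float_format="%.6f")
        classify.roc_to_frame(report).to_csv(
            out / "roc.csv", index=False, float_format="%.6f")
        feat_df = pd.DataFrame(X, columns=features.FEATURE_NAMES)
        feat_df.insert(0, "label", y)
        feat_df.to_csv(out / "features.csv", index=False, float_format="%.9g")
        cfg.to_yaml(out / "config.yaml")
        logger.info("reports written to %s", out)
    return report, comparison
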
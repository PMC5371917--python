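"""Bagged decision trees and cross-validated evaluation.

The ensemble follows the classical bootstrap-aggregating recipe: each of
``n_trees`` (default 40) unpruned Gini CART trees is trained on a bag — a
with-replacement resample of the training set of the same size — and
prediction is by majority vote, ties broken by the fixed class order.
Evaluation is repeated stratified K-fold cross-validation (default K=10,
10 repeats) with a pooled confusion matrix and one-vs-rest macro AUC,
plus a comparison harness running six reference classifiers on identical
fold assignments.
"""

from __future__ import annotations

import hashlib
import time
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_X_y, check_array

from .exceptions import ParameterError
from .features import MANIFEST_VERSION, FEATURE_NAMES
from .io_accel import CLASS_ORDER

#: Split budgets for the single-tree baselines in the comparison harness;
#: a tree with S binary splits has S + 1 leaves.
COMPARISON_CONFIG = {
    "complex_tree": {"max_splits": 100},
    "simple_tree": {"max_splits": 4},
    "boosted_trees": {"n_learners": 30},
    "bagged_trees": {"n_learners": 40},
}


class BaggedTreesClassifier(BaseEstimator, ClassifierMixin):
    """Bootstrap-aggregated decision trees with majority voting.

    Parameters
    ----------
    n_trees : int
        Ensemble size (40 in the reference configuration).
    bootstrap : bool
        If False (test hook), every tree sees the full training set, so a
        single-tree ensemble reduces exactly to one decision tree.
    class_order : sequence of labels, optional
        Fixed label ordering used for vote columns and tie-breaking
        (first label wins a tied vote). Defaults to sorted unique labels,
        or the canonical behavior ordering when the labels match it.
    random_state : int, optional
        Seeds both the bootstrap resampling and the trees.
    """

    def __init__(self, n_trees: int = 40, bootstrap: bool = True,
                 class_order: Optional[Sequence] = None,
                 random_state: Optional[int] = None):
        self.n_trees = n_trees
        self.bootstrap = bootstrap
        self.class_order = class_order
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.n_trees < 1:
            raise ParameterError("n_trees must be >= 1")
        uniq = np.unique(y)
        if len(uniq) < 2:
            raise ParameterError("training data contains a single class")
        if self.class_order is not None:
            order = list(self.class_order)
            if set(uniq) - set(order):
                raise ParameterError("labels outside the given class_order")
        elif set(uniq) == set(CLASS_ORDER):
            order = list(CLASS_ORDER)
        else:
            order = list(uniq)
        self.classes_ = np.asarray(order)
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        self.trees_ = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n) if self.bootstrap else np.arange(n)
            tree = DecisionTreeClassifier(
                criterion="gini",
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted_X(self, X):
        if not hasattr(self, "trees_"):
            raise ParameterError("classifier not fitted")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ParameterError(
                f"X has {X.shape[1]} columns, model was trained on {self.n_features_in_}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Per-class vote fractions (rows sum to 1)."""
        X = self._check_fitted_X(X)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        col = {c: j for j, c in enumerate(self.classes_)}
        for tree in self.trees_:
            pred = tree.predict(X)
            for i, p in enumerate(pred):
                votes[i, col[p]] += 1
        return votes / self.n_trees

    def predict(self, X) -> np.ndarray:
        """Majority-vote label; ties resolved to the first class in order."""
        frac = self.predict_proba(X)
        return self.classes_[np.argmax(frac, axis=1)]


@dataclass
class CVReport:
    """Pooled results of repeated stratified K-fold cross-validation."""

    class_order: list
    confusion: np.ndarray            # (C, C) counts pooled over folds+repeats
    per_class_accuracy: np.ndarray   # recall per class
    overall_accuracy: float
    auc: float                       # one-vs-rest macro AUC on pooled scores
    per_fold_indices: list           # [(repeat, fold, test_indices), ...]
    n_repeats: int
    per_repeat_accuracy: np.ndarray = field(default_factory=lambda: np.array([]))
    roc_curves: dict = field(default_factory=dict)  # class -> (fpr, tpr, auc)

    def validate(self) -> None:
        total = self.confusion.sum()
        acc = np.trace(self.confusion) / total
        if abs(acc - self.overall_accuracy) > 1e-12:
            from .exceptions import InvariantError

            raise InvariantError("overall_accuracy inconsistent with confusion matrix")


def train_bagged_trees(X, y, n_trees: int = 40, seed: Optional[int] = None,
                       bootstrap: bool = True) -> BaggedTreesClassifier:
    """Thin functional wrapper over :class:`BaggedTreesClassifier`."""
    return BaggedTreesClassifier(n_trees=n_trees, bootstrap=bootstrap,
                                 random_state=seed).fit(X, y)


def predict(model: BaggedTreesClassifier, X):
    """Labels plus per-class vote fractions."""
    return model.predict(X), model.predict_proba(X)


def roc_auc_ovr(y_true, scores, class_order: Sequence):
    """One-vs-rest ROC per class and the macro-average AUC.

    ``scores`` columns follow ``class_order``. A class absent from
    ``y_true`` has no defined ROC; it is excluded from the macro average
    with a warning.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    curves = {}
    aucs = []
    for j, cls in enumerate(class_order):
        pos = y_true == cls
        if pos.sum() == 0 or pos.sum() == len(y_true):
            warnings.warn(f"class {cls!r} absent (or alone) in y_true; AUC undefined")
            continue
        fpr, tpr, _ = _sk_roc_curve(pos.astype(int), scores[:, j])
        a = float(_auc(fpr, tpr))
        curves[cls] = (fpr, tpr, a)
        aucs.append(a)
    macro = float(np.mean(aucs)) if aucs else float("nan")
    return macro, curves


def repeated_kfold_cv(
    X,
    y,
    K: int = 10,
    n_repeats: int = 10,
    n_trees: int = 40,
    seed: int = 0,
    model: Optional[BaseEstimator] = None,
) -> CVReport:
    """Repeated stratified K-fold cross-validation of the bagged ensemble.

    Every sample is tested exactly once per repeat; the confusion matrix is
    pooled over folds and repeats, so (with equal per-repeat sample counts)
    ``trace/sum`` equals the mean over repeats of per-repeat accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < K:
        raise ParameterError(
            f"smallest class has {counts.min()} samples < K={K}; use a smaller K"
        )
    order = list(CLASS_ORDER) if set(classes) == set(CLASS_ORDER) else list(classes)

    confusion = np.zeros((len(order), len(order)), dtype=int)
    fold_indices = []
    per_repeat_acc = []
    pooled_true = []
    pooled_scores = []
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed + r)
        y_pred_rep = np.empty(len(y), dtype=y.dtype)
        for f, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            if model is None:
                est = BaggedTreesClassifier(
                    n_trees=n_trees, class_order=order,
                    random_state=int(1_000_003 * r + 7 * f + seed),
                )
            else:
                est = clone(model)
                if "random_state" in est.get_params():
                    est.set_params(random_state=int(1_000_003 * r + 7 * f + seed))
            est.fit(X[train_idx], y[train_idx])
            pred = est.predict(X[test_idx])
            y_pred_rep[test_idx] = pred
            scores = _scores_of(est, X[test_idx], order)
            pooled_true.append(y[test_idx])
            pooled_scores.append(scores)
            fold_indices.append((r, f, test_idx))
        confusion += _sk_confusion(y, y_pred_rep, labels=order)
        per_repeat_acc.append(float(np.mean(y_pred_rep == y)))

    row_sums = confusion.sum(axis=1)
    per_class = np.divide(np.diag(confusion), row_sums, where=row_sums > 0,
                          out=np.zeros(len(order), dtype=float))
    overall = float(np.trace(confusion) / confusion.sum())
    macro_auc, curves = roc_auc_ovr(
        np.concatenate(pooled_true), np.vstack(pooled_scores), order
    )
    report = CVReport(
        class_order=order,
        confusion=confusion,
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        auc=macro_auc,
        per_fold_indices=fold_indices,
        n_repeats=n_repeats,
        per_repeat_accuracy=np.asarray(per_repeat_acc),
        roc_curves=curves,
    )
    report.validate()
    return report


def _scores_of(est, X, order) -> np.ndarray:
    """Per-class scores aligned with ``order``, rows summing to 1.

    Vote fractions / probabilities where available; margin-based models
    (SVMs) expose one-vs-rest decision values, mapped through a softmax.
    """
    if hasattr(est, "predict_proba"):
        proba = np.asarray(est.predict_proba(X), dtype=float)
    else:
        d = np.asarray(est.decision_function(X), dtype=float)
        if d.ndim == 1:  # binary: one margin column
            d = np.column_stack([-d, d])
        d = d - d.max(axis=1, keepdims=True)
        proba = np.exp(d)
        proba /= proba.sum(axis=1, keepdims=True)
    cols = [list(est.classes_).index(c) for c in order]
    return proba[:, cols]


def _comparison_models(seed: int) -> dict:
    cfg = COMPARISON_CONFIG
    return {
        "complex_tree": DecisionTreeClassifier(
            max_leaf_nodes=cfg["complex_tree"]["max_splits"] + 1, random_state=seed),
        "simple_tree": DecisionTreeClassifier(
            max_leaf_nodes=cfg["simple_tree"]["max_splits"] + 1, random_state=seed),
        "linear_svm": SVC(kernel="linear", random_state=seed),
        "gaussian_svm": SVC(kernel="rbf", random_state=seed),
        "boosted_trees": AdaBoostClassifier(
            n_estimators=cfg["boosted_trees"]["n_learners"], random_state=seed),
        "bagged_trees": BaggedTreesClassifier(
            n_trees=cfg["bagged_trees"]["n_learners"], random_state=seed),
    }


def compare_classifiers(X, y, K: int = 10, seed: int = 0) -> pd.DataFrame:
    """Evaluate the six reference classifiers on identical fold assignments.

    Returns a table with one row per model: accuracy, macro one-vs-rest AUC,
    total training wall-time over folds, and a hash of the shared fold
    assignment (identical across rows by construction). A model failure is
    recorded as NaN in its row without aborting the table.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    order = list(CLASS_ORDER) if set(classes) == set(CLASS_ORDER) else list(classes)
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    fold_hash = hashlib.sha256(
        b"".join(np.sort(te).tobytes() for _, te in folds)
    ).hexdigest()[:12]

    rows = []
    for name, proto in _comparison_models(seed).items():
        try:
            y_pred = np.empty(len(y), dtype=y.dtype)
            pooled_true, pooled_scores = [], []
            t_train = 0.0
            for train_idx, test_idx in folds:
                est = clone(proto)
                t0 = time.perf_counter()
                est.fit(X[train_idx], y[train_idx])
                t_train += time.perf_counter() - t0
                y_pred[test_idx] = est.predict(X[test_idx])
                pooled_true.append(y[test_idx])
                pooled_scores.append(_scores_of(est, X[test_idx], order))
            acc = float(np.mean(y_pred == y))
            macro_auc, _ = roc_auc_ovr(np.concatenate(pooled_true),
                                       np.vstack(pooled_scores), order)
            rows.append({"model": name, "accuracy": acc, "auc": macro_auc,
                         "train_time_s": t_train, "fold_hash": fold_hash})
        except Exception as e:  # keep the table going, record the failure
            warnings.warn(f"model {name} failed: {e}")
            rows.append({"model": name, "accuracy": np.nan, "auc": np.nan,
                         "train_time_s": np.nan, "fold_hash": fold_hash})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report export and model persistence


def confusion_to_frame(report: CVReport) -> pd.DataFrame:
    """Confusion matrix as a table: counts with row percentages, one row per
    true class plus an overall row (layout mirrors a standard per-class
    accuracy table)."""
    rows = []
    for i, cls in enumerate(report.class_order):
        row = {"class": cls}
        total = report.confusion[i].sum()
        for j, pred_cls in enumerate(report.class_order):
            c = int(report.confusion[i, j])
            pct = 100.0 * c / total if total else 0.0
            row[pred_cls] = f"{c} ({pct:.0f}%)"
        row["accuracy"] = f"{100.0 * report.per_class_accuracy[i]:.1f}%"
        rows.append(row)
    rows.append({"class": "overall",
                 **{c: "" for c in report.class_order},
                 "accuracy": f"{100.0 * report.overall_accuracy:.1f}%"})
    return pd.DataFrame(rows)


def roc_to_frame(report: CVReport) -> pd.DataFrame:
    """ROC curve points as long-form (class, fpr, tpr) rows."""
    rows = []
    for cls, (fpr, tpr, a) in report.roc_curves.items():
        for f, t in zip(fpr, tpr):
            rows.append({"class": cls, "fpr": float(f), "tpr": float(t), "auc": a})
    return pd.DataFrame(rows)


def save_model(model: BaggedTreesClassifier, path) -> None:
    """Persist a fitted ensemble together with the feature-manifest version."""
    joblib.dump(
        {"model": model, "manifest_version": MANIFEST_VERSION,
         "feature_names": list(FEATURE_NAMES)},
        path,
    )


def load_model(path) -> BaggedTreesClassifier:
    """Load a persisted ensemble, refusing a mismatched feature manifest."""
    blob = joblib.load(path)
    if blob.get("manifest_version") != MANIFEST_VERSION or \
            blob.get("feature_names") != list(FEATURE_NAMES):
        raise ParameterError(
            f"model was trained with feature manifest "
            f"{blob.get('manifest_version')!r}, package has {MANIFEST_VERSION!r}"
        )
    return blob["model"]
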
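"""Noise-normalized cross-validation, ROC/AUC, the architecture benchmark
grid, and leave-one-feature-out ablation.

Replicate observations share a guide's feature vector but may disagree in
quartile label; no classifier can beat the ceiling this imposes. The
ceiling is::

    max_nn = 1 - |{(i,j) : x_i = x_j, y_i != y_j}| / |{(i,j) : x_i = x_j}|

over unordered distinct row pairs with identical feature vectors, and the
noise-normalized accuracy is ``acc_nn = acc / max_nn``.

Two CV schemes mirror the protocol the training data was evaluated under:

* ``threefold_replicate`` — one fold per experimental replicate: train on
  two replicates, test on the held-out third, average the three rotations;
* ``fivefold_random`` — per repeat, pool all replicate rows, draw a random
  80/20 split, test on the 20%; accuracies average over repeats (100 by
  convention). True rotating 5-fold is available via ``rotating=True``.

Per-class AUC is one-vs-all on pooled out-of-fold scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .features import FeatureMatrix
from .model import make_estimator

logger = logging.getLogger(__name__)


@dataclass
class NoiseCeiling:
    conflicting_pairs: int
    total_pairs: int
    max_nn: float
    measurable: bool = True  # False when no identical-feature pairs exist


def noise_ceiling(
    rows: np.ndarray,
    labels: Sequence[int],
    groups: Sequence | None = None,
) -> NoiseCeiling:
    """Replicate-label noise ceiling.

    Rows are grouped by exact feature-vector equality (or by an explicit
    ``groups`` vector, e.g. guide IDs). Within each group all unordered
    distinct pairs are counted; conflicting pairs are those with different
    labels. With no identical-feature pairs the ceiling is 1 by convention
    (no noise is measurable) and flagged.
    """
    rows = np.asarray(rows)
    labels = np.asarray(labels)
    if rows.shape[0] != len(labels):
        raise ValueError("rows and labels differ in length")
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if groups is None:
        keys = [r.tobytes() for r in np.ascontiguousarray(rows, dtype=float)]
    else:
        if len(groups) != len(labels):
            raise ValueError("groups length != labels length")
        keys = list(groups)
    by_key: dict = {}
    for key, y in zip(keys, labels):
        by_key.setdefault(key, []).append(y)
    total = 0
    conflicting = 0
    for ys in by_key.values():
        m = len(ys)
        if m < 2:
            continue
        total += m * (m - 1) // 2
        _, counts = np.unique(np.asarray(ys), return_counts=True)
        same = int((counts * (counts - 1) // 2).sum())
        conflicting += m * (m - 1) // 2 - same
    if total == 0:
        logger.warning("no identical-feature pairs: noise ceiling set to 1")
        return NoiseCeiling(0, 0, 1.0, measurable=False)
    return NoiseCeiling(conflicting, total, 1.0 - conflicting / total)


@dataclass
class CVReport:
    scheme: str
    repeats: int
    raw_accuracy: float
    noise_normalized_accuracy: float
    max_nn: float
    per_fold: list[float]
    per_class_auc: dict[int, float]
    best_hyperparameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "repeats": self.repeats,
            "raw_accuracy": self.raw_accuracy,
            "noise_normalized_accuracy": self.noise_normalized_accuracy,
            "max_nn": self.max_nn,
            "per_fold": self.per_fold,
            "per_class_auc": {str(k): v for k, v in self.per_class_auc.items()},
            "best_hyperparameters": self.best_hyperparameters,
        }


def roc_one_vs_all(scores: np.ndarray, labels: Sequence[int]) -> dict[int, float]:
    """Per-class one-vs-all AUC by midrank (trapezoid) scoring. Classes
    absent from ``labels`` get nan and a warning."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape[0] != len(labels):
        raise ValueError("scores rows != labels length")
    if scores.ndim != 2 or scores.shape[1] != 4:
        raise ValueError("scores must be n x 4")
    auc: dict[int, float] = {}
    for c in range(4):
        indicator = (labels == c).astype(int)
        if indicator.min() == indicator.max():
            logger.warning("class %d absent (or exhaustive) in labels: AUC undefined", c)
            auc[c] = float("nan")
            continue
        auc[c] = float(roc_auc_score(indicator, scores[:, c]))
    return auc


def _fit_score(spec: Mapping, X_train, y_train, X_test, y_test, seed: int) -> float:
    est = make_estimator(spec["architecture"], spec.get("hyperparameters"), seed)
    est.fit(X_train, y_train)
    return float(np.mean(est.predict(X_test) == y_test))


def _scores_for_auc(spec: Mapping, X_train, y_train, X_test, seed: int) -> np.ndarray:
    est = make_estimator(spec["architecture"], spec.get("hyperparameters"), seed)
    est.fit(X_train, y_train)
    classes = np.asarray(est.classes_, dtype=int)
    out = np.zeros((X_test.shape[0], 4))
    if hasattr(est, "predict_proba"):
        out[:, classes] = est.predict_proba(X_test)
    else:
        margins = np.atleast_2d(est.decision_function(X_test))
        if margins.shape[1] == 1:
            margins = np.column_stack([-margins[:, 0], margins[:, 0]])
        exp = np.exp(margins - margins.max(axis=1, keepdims=True))
        out[:, classes] = exp / exp.sum(axis=1, keepdims=True)
    return out


def cross_validate(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    model_spec: Mapping,
    scheme: str = "fivefold_random",
    repeats: int = 100,
    seed: int = 0,
    replicate_ids: Sequence[int] | None = None,
    groups: Sequence | None = None,
    param_sweep: Mapping[str, Sequence] | None = None,
    rotating: bool = False,
    compute_auc: bool = True,
) -> CVReport:
    """Run one CV scheme and return raw and noise-normalized accuracy.

    ``model_spec``: {"architecture": ..., "hyperparameters": {...}}.
    ``param_sweep``: optional {hyperparameter: values}; per fold/repeat the
    best value by test accuracy is used and the average best value is
    reported (the benchmark table's bracket convention).
    The ceiling uses the full dataset (``groups`` for explicit guide-ID
    grouping, else exact feature equality).
    """
    X = matrix.values
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    ceiling = noise_ceiling(X, y, groups=groups)

    fold_accs: list[float] = []
    best_params: list[float] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    sweep_name = next(iter(param_sweep)) if param_sweep else None

    def run_fold(train_idx: np.ndarray, test_idx: np.ndarray, fold_seed: int) -> None:
        spec = dict(model_spec)
        if sweep_name:
            base_hp = dict(spec.get("hyperparameters") or {})
            accs = []
            for value in param_sweep[sweep_name]:
                s = dict(spec, hyperparameters={**base_hp, sweep_name: value})
                accs.append(
                    _fit_score(s, X[train_idx], y[train_idx], X[test_idx], y[test_idx],
                               fold_seed)
                )
            best_i = int(np.argmax(accs))
            best_params.append(param_sweep[sweep_name][best_i])
            fold_accs.append(accs[best_i])
            spec = dict(
                spec,
                hyperparameters={**base_hp, sweep_name: param_sweep[sweep_name][best_i]},
            )
        else:
            fold_accs.append(
                _fit_score(spec, X[train_idx], y[train_idx], X[test_idx], y[test_idx],
                           fold_seed)
            )
        if compute_auc:
            pooled_scores.append(
                _scores_for_auc(spec, X[train_idx], y[train_idx], X[test_idx], fold_seed)
            )
            pooled_labels.append(y[test_idx])

    if scheme == "threefold_replicate":
        if replicate_ids is None:
            raise ValueError("threefold_replicate needs replicate_ids")
        replicate_ids = np.asarray(replicate_ids)
        reps = np.unique(replicate_ids)
        if len(reps) != 3:
            raise ValueError(f"threefold_replicate needs exactly 3 replicates, got {len(reps)}")
        for i, rep in enumerate(reps):
            test_idx = np.flatnonzero(replicate_ids == rep)
            train_idx = np.flatnonzero(replicate_ids != rep)
            run_fold(train_idx, test_idx, seed + i)
        repeats_done = 3
    elif scheme == "fivefold_random":
        if repeats < 1:
            raise ValueError("repeats must be >= 1")
        n = len(y)
        for r in range(repeats):
            perm = rng.permutation(n)
            if rotating:
                folds = np.array_split(perm, 5)
                for f, test_idx in enumerate(folds):
                    train_idx = np.setdiff1d(perm, test_idx)
                    run_fold(train_idx, test_idx, seed + 31 * r + f)
            else:
                cut = int(round(0.8 * n))
                run_fold(perm[:cut], perm[cut:], seed + r)
        repeats_done = repeats
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    acc = float(np.mean(fold_accs))
    acc_nn = acc / ceiling.max_nn if ceiling.max_nn > 0 else float("nan")
    auc = (
        roc_one_vs_all(np.vstack(pooled_scores), np.concatenate(pooled_labels))
        if compute_auc and pooled_scores
        else {c: float("nan") for c in range(4)}
    )
    best = {}
    if sweep_name and best_params:
        best = {sweep_name: float(np.mean(best_params))}
    return CVReport(
        scheme=scheme,
        repeats=repeats_done,
        raw_accuracy=acc,
        noise_normalized_accuracy=acc_nn,
        max_nn=ceiling.max_nn,
        per_fold=fold_accs,
        per_class_auc=auc,
        best_hyperparameters=best,
    )


#: benchmark sweep ranges (the printed best values fall inside them)
KNN_SWEEP = {"n_neighbors": list(range(1, 16))}
RF_SWEEP = {"n_estimators": list(range(10, 101, 10))}


def benchmark_grid(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    feature_lists: Mapping[str, Sequence[str]],
    architectures: Sequence[str] = (
        "random_forest", "knn", "svc_linear", "svc_poly", "svc_sigmoid",
        "svc_rbf", "decision_tree",
    ),
    schemes: Sequence[str] = ("threefold_replicate", "fivefold_random"),
    repeats: int = 100,
    seed: int = 0,
    replicate_ids: Sequence[int] | None = None,
    groups: Sequence | None = None,
    sweep: bool = True,
) -> "pd.DataFrame":
    """Architectures x feature lists x CV schemes accuracy grid.

    Cells hold raw accuracy; knn and random_forest cells also record the
    averaged best swept parameter. Empty feature lists yield NaN cells.
    """
    import pandas as pd

    rows = []
    for scheme in schemes:
        for arch in architectures:
            row: dict = {"scheme": scheme, "architecture": arch}
            for list_name, names in feature_lists.items():
                if not names:
                    row[list_name] = float("nan")
                    continue
                sub = matrix.subset(list(names))
                param_sweep = None
                if sweep and arch == "knn":
                    param_sweep = KNN_SWEEP
                elif sweep and arch == "random_forest":
                    param_sweep = RF_SWEEP
                report = cross_validate(
                    sub, labels, {"architecture": arch}, scheme=scheme,
                    repeats=repeats, seed=seed, replicate_ids=replicate_ids,
                    groups=groups, param_sweep=param_sweep, compute_auc=False,
                )
                row[list_name] = report.raw_accuracy
                if report.best_hyperparameters:
                    key = next(iter(report.best_hyperparameters))
                    row[f"{list_name}|best_{key}"] = report.best_hyperparameters[key]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AblationReport:
    background_mean: float
    per_feature_delta: dict[str, float]
    repeats: int

    def to_dict(self) -> dict:
        return {
            "background_mean": self.background_mean,
            "repeats": self.repeats,
            "per_feature_delta": self.per_feature_delta,
        }


def feature_ablation(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    model_spec: Mapping,
    repeats: int = 100,
    seed: int = 0,
) -> AblationReport:
    """Leave-one-feature-out ablation.

    Background = mean accuracy over ``repeats`` random 80/20 runs on the
    full list; each feature's delta = background minus the mean over
    ``repeats`` runs without it (positive delta: removing the feature
    hurts). Total fits = repeats * (1 + number of features).
    """
    if len(matrix.descriptors) < 2:
        raise ValueError("ablation needs at least 2 features")

    def mean_acc(sub: FeatureMatrix, run_seed: int) -> float:
        report = cross_validate(
            sub, labels, model_spec, scheme="fivefold_random",
            repeats=repeats, seed=run_seed, compute_auc=False,
        )
        return report.raw_accuracy

    background = mean_acc(matrix, seed)
    deltas: dict[str, float] = {}
    for name in matrix.names:
        reduced = matrix.subset([n for n in matrix.names if n != name])
        deltas[name] = background - mean_acc(reduced, seed)
    return AblationReport(background, deltas, repeats)
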
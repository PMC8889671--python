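"""Quartile efficacy classes, the classifier zoo, and ranked predictions.

Normalized target expression in [0,1] (lower = better knockdown) is binned
into four quartile classes:

===== ================== ==================
code  label              expression bin
===== ================== ==================
0     highly_efficient   [0.00, 0.25)
1     efficient          [0.25, 0.50)
2     inefficient        [0.50, 0.75)
3     highly_inefficient [0.75, 1.00]
===== ================== ==================

Boundary values go to the higher class; 1.0 is capped into class 3.

Seven architectures are supported for benchmarking; the production
configuration is a Gini-impurity decision tree over the random-forest-Gini
feature list. Each guide contributes one training row per replicate
(identical features, possibly different labels) — that deliberate
duplication is what makes the replicate-noise ceiling bind during
evaluation.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureDescriptor, FeatureMatrix
from .guide_space import GuideCandidate

logger = logging.getLogger(__name__)

CLASS_LABELS = {
    0: "highly_efficient",
    1: "efficient",
    2: "inefficient",
    3: "highly_inefficient",
}

#: classes written to per-transcript prediction files ("at least efficient")
EFFICIENT_CLASSES = (0, 1)

ARCHITECTURES = (
    "decision_tree",
    "random_forest",
    "knn",
    "svc_linear",
    "svc_poly",
    "svc_sigmoid",
    "svc_rbf",
)


@dataclass(frozen=True)
class EfficacyClass:
    code: int

    def __post_init__(self) -> None:
        if self.code not in CLASS_LABELS:
            raise ValueError(f"invalid class code {self.code}")

    @property
    def label(self) -> str:
        return CLASS_LABELS[self.code]


def assign_class(expression: float) -> EfficacyClass:
    """Quartile-bin a normalized expression value (half-open bins, 1.0 -> 3)."""
    if not 0.0 <= expression <= 1.0:
        raise ValueError(f"expression {expression} outside [0,1]")
    return EfficacyClass(min(int(expression * 4), 3))


@dataclass(frozen=True)
class KnockdownObservation:
    """One (guide, replicate) normalized-expression measurement."""

    guide_id: str
    replicate_id: int
    expression: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.expression <= 1.0:
            raise ValueError(
                f"{self.guide_id} rep {self.replicate_id}: expression "
                f"{self.expression} outside [0,1]"
            )

    @property
    def efficacy_class(self) -> EfficacyClass:
        return assign_class(self.expression)


def make_estimator(architecture: str, hyperparameters: Mapping | None, seed: int):
    hp = dict(hyperparameters or {})
    if architecture == "decision_tree":
        return DecisionTreeClassifier(criterion="gini", random_state=seed, **hp)
    if architecture == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(
            criterion="gini", random_state=seed, n_jobs=1, **hp
        )
    if architecture == "knn":
        hp.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**hp)
    if architecture.startswith("svc_"):
        kernel = architecture.removeprefix("svc_")
        if kernel not in {"linear", "poly", "sigmoid", "rbf"}:
            raise ValueError(f"unknown architecture {architecture!r}")
        return SVC(kernel=kernel, random_state=seed, **hp)
    raise ValueError(f"unknown architecture {architecture!r}")


@dataclass
class TrainedModel:
    """A fitted classifier bound to an explicit ordered feature list.

    ``training_fingerprint`` hashes (data, features, architecture, seed) so
    that identical training inputs are recognizably identical models.
    """

    architecture: str
    hyperparameters: dict
    feature_list: list[FeatureDescriptor]
    estimator: object
    seed: int
    training_fingerprint: str

    @property
    def feature_names(self) -> list[str]:
        return [d.name for d in self.feature_list]

    def _check_matrix(self, matrix: FeatureMatrix) -> None:
        if matrix.names != self.feature_names:
            missing = set(self.feature_names) - set(matrix.names)
            extra = set(matrix.names) - set(self.feature_names)
            raise ValueError(
                f"feature mismatch: missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]}"
            )

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        self._check_matrix(matrix)
        return np.asarray(self.estimator.predict(matrix.values), dtype=int)

    def class_scores(self, matrix: FeatureMatrix) -> np.ndarray:
        """Per-class membership scores, one column per class 0..3.

        Decision tree: training-class fractions in the reached leaf; random
        forest / knn: the analogous averaged fractions. SVC (fitted without
        probability calibration) falls back to a softmax over one-vs-rest
        decision margins — a monotone ranking score, not a calibrated
        probability.
        """
        self._check_matrix(matrix)
        est = self.estimator
        classes = np.asarray(est.classes_, dtype=int)
        n = matrix.values.shape[0]
        out = np.zeros((n, 4))
        if hasattr(est, "predict_proba"):
            out[:, classes] = est.predict_proba(matrix.values)
        else:
            margins = np.atleast_2d(est.decision_function(matrix.values))
            if margins.shape[1] == 1:  # binary: one margin column
                margins = np.column_stack([-margins[:, 0], margins[:, 0]])
            exp = np.exp(margins - margins.max(axis=1, keepdims=True))
            out[:, classes] = exp / exp.sum(axis=1, keepdims=True)
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def _fingerprint(values: np.ndarray, labels: np.ndarray, names: Sequence[str],
                 architecture: str, seed: int) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(values).tobytes())
    h.update(np.ascontiguousarray(labels).tobytes())
    h.update("\x00".join(names).encode())
    h.update(f"{architecture}|{seed}".encode())
    return h.hexdigest()[:16]


def train(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    architecture: str = "decision_tree",
    hyperparameters: Mapping | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit one architecture on the matrix; deterministic given seed."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(matrix.row_ids):
        raise ValueError("labels length != row count")
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs at least 2 classes")
    est = make_estimator(architecture, hyperparameters, seed)
    est.fit(matrix.values, labels)
    return TrainedModel(
        architecture=architecture,
        hyperparameters=dict(hyperparameters or {}),
        feature_list=list(matrix.descriptors),
        estimator=est,
        seed=seed,
        training_fingerprint=_fingerprint(
            matrix.values, labels, matrix.names, architecture, seed
        ),
    )


@dataclass
class GuidePrediction:
    guide: GuideCandidate
    predicted_class: EfficacyClass
    confidence: float
    rank: int | None = None  # assigned within the transcript's efficient set


def predict_guides(
    model: TrainedModel,
    guides_matrix: FeatureMatrix,
    guides: Sequence[GuideCandidate],
) -> list[GuidePrediction]:
    """Classify every guide; confidence is the predicted class's membership
    score. Ranks (1..n, descending confidence, ties broken by ascending
    target_start) are assigned per transcript over the at-least-efficient
    subset — the classes that reach the output files."""
    if [g.guide_id for g in guides] != list(guides_matrix.row_ids):
        raise ValueError("guides and matrix rows disagree in order or identity")
    scores = model.class_scores(guides_matrix)
    pred = scores.argmax(axis=1)
    predictions = [
        GuidePrediction(g, EfficacyClass(int(c)), float(s[c]))
        for g, c, s in zip(guides, pred, scores)
    ]
    # per-transcript ranking over the efficient subset
    by_transcript: dict[str, list[GuidePrediction]] = {}
    for p in predictions:
        if p.predicted_class.code in EFFICIENT_CLASSES:
            by_transcript.setdefault(p.guide.source_transcript, []).append(p)
    for plist in by_transcript.values():
        plist.sort(key=lambda p: (-p.confidence, p.guide.target_start))
        for i, p in enumerate(plist, start=1):
            p.rank = i
    return predictions


def write_prediction_files(
    predictions: Sequence[GuidePrediction],
    out_dir: str | Path,
    header_lines: Sequence[str] = (),
) -> dict[str, Path]:
    """One tab-delimited file per transcript with its ranked at-least-
    efficient guides; transcripts whose guides are all inefficient get an
    empty file and a warning."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_transcript: dict[str, list[GuidePrediction]] = {}
    for p in predictions:
        by_transcript.setdefault(p.guide.source_transcript, []).append(p)
    written: dict[str, Path] = {}
    for tid, plist in sorted(by_transcript.items()):
        efficient = sorted(
            (p for p in plist if p.rank is not None), key=lambda p: p.rank
        )
        path = out_dir / f"{tid}.guides.tsv"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("rank\tspacer\ttarget_start\tpredicted_class\tconfidence\n")
            for p in efficient:
                fh.write(
                    f"{p.rank}\t{p.guide.spacer}\t{p.guide.target_start}\t"
                    f"{p.predicted_class.code}\t{p.confidence:.6f}\n"
                )
        if not efficient:
            logger.warning("transcript %s: no guides predicted at least efficient", tid)
        written[tid] = path
    return written
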
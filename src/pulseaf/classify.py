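"""Training and evaluation of the binary AF classifier.

Evaluation follows the confusion-matrix convention with AF as the positive
class: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy,
precision, F-score, and ROC AUC by trapezoidal integration over all score
thresholds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import ConfigurationError
from .estimators import MODEL_REGISTRY, AFDetector, FeatureExtractor
from .features import TARGET_NAME
from .select import FeatureGroup, get_feature_group
from .simulate import AF

__all__ = [
    "ClassificationReport", "SplitSpec", "TrainResult", "build_feature_table",
    "train_classifier", "evaluate_classifier", "roc_curve_points",
]


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and the derived performance fractions."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f_score: float
    roc_auc: float
    threshold: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test protocol: stratified holdout (default 70/30) or k-fold."""

    scheme: str = "holdout"
    test_fraction: float = 0.3
    folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("holdout", "kfold"):
            raise ConfigurationError(f"unknown split scheme {self.scheme!r}")
        if not (0 < self.test_fraction < 1):
            raise ConfigurationError("test_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")


@dataclass
class TrainResult:
    """Fitted model handle plus held-out labels and scores."""

    detector: AFDetector
    labels: np.ndarray
    scores: np.ndarray
    split: SplitSpec
    manifest: dict = field(default_factory=dict)


def build_feature_table(
    records,
    group: FeatureGroup | str | None = None,
    extractor: FeatureExtractor | None = None,
) -> pd.DataFrame:
    """Run the full extraction pipeline over labeled records.

    ``records`` yields ``(WaveformSignal, label)`` pairs where the label is a
    rhythm string ('AF'/'NSR'), a GroundTruth, or a 0/1 integer. One row per
    record with the group's feature columns plus the binary target Vt;
    records failing beat detection are dropped with a logged reason.
    """
    extractor = extractor or FeatureExtractor()
    signals, labels = [], []
    for signal, label in records:
        if hasattr(label, "rhythm_label"):
            label = label.rhythm_label
        if isinstance(label, str):
            label = 1 if label.upper() == AF else 0
        signals.append(signal)
        labels.append(int(label))
    table = extractor.transform(signals)
    kept = [i for i in range(len(signals)) if i not in set(extractor.failed_indices_)]
    if group is not None:
        if isinstance(group, str):
            group = get_feature_group(group)
        table = table[list(group.members)]
    table[TARGET_NAME] = np.asarray(labels)[kept]
    if table.empty:
        raise ConfigurationError("no records survived feature extraction")
    return table


def train_classifier(
    table: pd.DataFrame,
    model: str = "gradient_boosting",
    split: SplitSpec | None = None,
    feature_group: str | None = None,
) -> TrainResult:
    """Fit a classifier on the train partition; return held-out scores.

    With the default holdout scheme the model handle is fit on the training
    portion only; with k-fold, held-out scores are pooled across folds and
    the returned handle is refit on the full table for downstream use.
    """
    split = split or SplitSpec()
    if model not in MODEL_REGISTRY:
        raise ConfigurationError(f"unknown model {model!r}; valid: {sorted(MODEL_REGISTRY)}")
    y = table[TARGET_NAME].to_numpy().astype(int)
    x = table.drop(columns=[TARGET_NAME])
    if np.unique(y).size < 2:
        raise ConfigurationError("both classes must be present to train")
    detector = AFDetector(model=model, feature_group=feature_group, random_state=split.seed)
    if split.scheme == "holdout":
        stratify = y if split.stratified else None
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, test_size=split.test_fraction, random_state=split.seed, stratify=stratify
        )
        if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
            raise ConfigurationError("degenerate partition: a split lost one class")
        detector.fit(x_tr, y_tr)
        labels, scores = y_te, detector.decision_scores(x_te)
    else:
        cv = StratifiedKFold(n_splits=split.folds, shuffle=True, random_state=split.seed)
        labels_parts, score_parts = [], []
        for tr_idx, te_idx in cv.split(x, y):
            if np.unique(y[tr_idx]).size < 2:
                raise ConfigurationError("degenerate partition: a fold lost one class")
            fold_det = detector.clone_unfitted().fit(x.iloc[tr_idx], y[tr_idx])
            labels_parts.append(y[te_idx])
            score_parts.append(fold_det.decision_scores(x.iloc[te_idx]))
        labels, scores = np.concatenate(labels_parts), np.concatenate(score_parts)
        detector.fit(x, y)
    manifest = {
        "model": model,
        "model_params": {k: repr(v) for k, v in detector.estimator_.get_params().items()},
        "split": asdict(split),
        "n_rows": int(len(table)),
        "columns": list(x.columns),
    }
    return TrainResult(detector, np.asarray(labels), np.asarray(scores), split, manifest)


def roc_curve_points(labels, scores) -> np.ndarray:
    """ROC curve as ordered (FPR, TPR) pairs from (0,0) to (1,1)."""
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ConfigurationError("ROC analysis needs both classes among the labels")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    if fpr[0] != 0 or tpr[0] != 0:
        fpr, tpr = np.insert(fpr, 0, 0.0), np.insert(tpr, 0, 0.0)
    return np.column_stack([fpr, tpr])


def evaluate_classifier(labels, scores, threshold: float = 0.5) -> ClassificationReport:
    """Confusion-matrix metrics at ``threshold`` plus trapezoidal ROC AUC.

    A score >= threshold predicts the positive (AF) class.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.size != scores.size:
        raise ConfigurationError("labels and scores must have equal length")
    if np.unique(labels).size < 2:
        raise ConfigurationError("AUC undefined: labels contain a single class")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / labels.size
    f_score = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    curve = roc_curve_points(labels, scores)
    auc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return ClassificationReport(tp, fp, tn, fn, sens, spec, acc, prec, f_score, auc, threshold)
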
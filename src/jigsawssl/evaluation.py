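"""Classification metrics, ROC/AUROC, and cross-validation summaries.

The positive class is neoplastic/precancerous (label 1).  Accuracy and F1
use the confusion-count closed forms

    accuracy = (TP + TN) / (TP + TN + FP + FN)
    F1       = 2 TP / (2 TP + FP + FN)

together with sensitivity, specificity and precision.  AUROC is the
Mann-Whitney probability that an out-of-distribution (or positive) sample's
score outranks an in-distribution (negative) one, with ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve

from .manifest import label_codes
from .trainer import TrainConfig, predict_proba, train

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "metrics",
           "roc_auc", "cross_validate", "evaluate_model"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    precision: float
    n: int
    undefined: tuple = ()

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy


def confusion(predictions, labels) -> ConfusionCounts:
    """Exact TP/TN/FP/FN counts for binary predictions."""
    pred = np.asarray(predictions, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if pred.shape != lab.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {lab.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(lab, (0, 1)).all()):
        raise ValueError("predictions and labels must be 0/1")
    tn, fp, fn, tp = confusion_matrix(lab, pred, labels=[0, 1]).ravel()
    return ConfusionCounts(TP=int(tp), TN=int(tn), FP=int(fp), FN=int(fn))


def _ratio(num, den, name, undefined):
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Closed-form metrics; zero-denominator ratios are NaN and flagged."""
    if counts.n < 1:
        raise ValueError("need at least one evaluated sample")
    undefined: list = []
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    return MetricsReport(
        accuracy=(tp + tn) / counts.n,
        f1=_ratio(2 * tp, 2 * tp + fp + fn, "f1", undefined),
        sensitivity=_ratio(tp, tp + fn, "sensitivity", undefined),
        specificity=_ratio(tn, tn + fp, "specificity", undefined),
        precision=_ratio(tp, tp + fp, "precision", undefined),
        n=counts.n,
        undefined=tuple(undefined),
    )


def roc_auc(scores, labels):
    """AUROC (Mann-Whitney with ties at 1/2) and the ROC curve points.

    Returns ``(auroc, curve)`` with ``curve`` a DataFrame of
    (threshold, fpr, tpr).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUROC")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    return auc, pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def evaluate_model(model, frames, labels) -> MetricsReport:
    """Frame-level metrics of a trained model on raw uint8 images."""
    probs = predict_proba(model, frames)
    pred = (probs[:, 1] > probs[:, 0]).astype(int)  # ties -> negative class
    return metrics(confusion(pred, np.asarray(labels, dtype=int)))


def cross_validate(manifest: pd.DataFrame, images: dict, config: TrainConfig,
                   k_list=(100.0, 50.0, 25.0, 12.5, 6.25), folds: int = 5):
    """Train and evaluate per (k, fold); summarise median and SD per metric.

    Evaluation is frame-level on the manifest's labelled test split.
    Returns ``(table, summary)`` DataFrames.
    """
    test = manifest[(manifest["split"] == "test") & manifest["label"].isin(["0", "1"])]
    test_frames = [images[p] for p in test["frame_path"]]
    test_labels = label_codes(test)
    rows = []
    for k in k_list:
        for fold in range(1, folds + 1):
            cfg = replace(config, k_fraction=float(k), fold=fold, n_folds=folds)
            res = train(manifest, cfg, images)
            rep = evaluate_model(res.model, test_frames, test_labels)
            rows.append({"k": k, "fold": fold, "accuracy": rep.accuracy,
                         "f1": rep.f1, "sensitivity": rep.sensitivity,
                         "specificity": rep.specificity,
                         "precision": rep.precision, "n": rep.n})
    table = pd.DataFrame(rows)
    summary = table.groupby("k")[
        ["accuracy", "f1", "sensitivity", "specificity", "precision"]
    ].agg(["median", "std"])
    return table, summary
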
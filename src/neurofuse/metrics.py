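"""Classification metrics: confusion matrix, per-class sensitivity and
specificity, macro recall/F1, one-vs-rest ROC/AUC (micro and macro averages),
and precision-recall with average precision.

Definitions are the standard ones: sensitivity_c = TP_c/(TP_c + FN_c),
specificity_c = TN_c/(TN_c + FP_c); ROC curves come from a one-vs-rest
threshold sweep over the predicted scores with trapezoidal AUC.  Aggregate
quantities are computed through scikit-learn; the ROC sweep itself is local
code so its endpoint and tie conventions are pinned here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score, precision_recall_curve, recall_score

from .image import InvalidParameterError


def roc_points(scores: np.ndarray, positives: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest ROC by threshold sweep: (FPR, TPR) from (1,1) down to (0,0).

    Thresholds sweep the distinct scores; endpoints (0,0) and (1,1) are always
    included.  Returned arrays are sorted by ascending FPR.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(positives, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidParameterError("ROC requires both positive and negative examples")
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(pos[order])
    fp = np.cumsum(~pos[order])
    # collapse ties: keep the last index of each distinct score
    distinct = np.flatnonzero(np.diff(scores[order], append=np.nan) != 0)
    tpr = np.concatenate([[0.0], tp[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fp[distinct] / n_neg])
    return fpr, tpr


def trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


@dataclass
class MetricsReport:
    """Complete evaluation of one prediction set; serializes to stable JSON."""

    confusion_matrix: np.ndarray
    accuracy: float
    macro_recall: float
    macro_f1: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    roc: dict[str, dict[str, list[float]]]  # class -> {"fpr": [...], "tpr": [...]}
    auc: dict[str, float]
    micro_auc: float
    macro_auc: float
    pr: dict[str, dict[str, list[float]]]
    average_precision: dict[str, float]
    class_names: tuple[str, ...] = ()
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "confusion_matrix": self.confusion_matrix.tolist(),
            "accuracy": self.accuracy,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "roc": self.roc,
            "auc": self.auc,
            "micro_auc": self.micro_auc,
            "macro_auc": self.macro_auc,
            "pr": self.pr,
            "average_precision": self.average_precision,
            "class_names": list(self.class_names),
            "extras": self.extras,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json())
        return path

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        d = json.loads(text)
        return cls(
            confusion_matrix=np.asarray(d["confusion_matrix"]),
            accuracy=d["accuracy"], macro_recall=d["macro_recall"],
            macro_f1=d["macro_f1"], sensitivity=d["sensitivity"],
            specificity=d["specificity"], roc=d["roc"], auc=d["auc"],
            micro_auc=d["micro_auc"], macro_auc=d["macro_auc"], pr=d["pr"],
            average_precision=d["average_precision"],
            class_names=tuple(d["class_names"]), extras=d["extras"])


def evaluate(predictions: np.ndarray, labels: np.ndarray,
             class_names: tuple[str, ...] | None = None) -> MetricsReport:
    """Score probability predictions against integer labels.

    ``predictions`` is (n, k) class-probability rows; predicted class is the
    argmax.  Works for any k >= 2 (the staging pipeline uses k = 4).
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels)
    if p.ndim != 2 or p.shape[0] != y.shape[0]:
        raise InvalidParameterError(
            f"predictions {p.shape} do not match {y.shape[0]} labels")
    k = p.shape[1]
    names = tuple(class_names) if class_names else tuple(f"class{i}" for i in range(k))
    yhat = p.argmax(axis=1)
    cm = _sk_confusion(y, yhat, labels=np.arange(k))
    total = cm.sum()
    accuracy = float(np.trace(cm)) / total
    macro_recall = float(recall_score(y, yhat, labels=np.arange(k),
                                      average="macro", zero_division=0))
    macro_f1 = float(f1_score(y, yhat, labels=np.arange(k),
                              average="macro", zero_division=0))
    sens, spec, roc, auc, pr, ap = {}, {}, {}, {}, {}, {}
    for c in range(k):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens[names[c]] = float(tp / (tp + fn)) if tp + fn else 0.0
        spec[names[c]] = float(tn / (tn + fp)) if tn + fp else 0.0
        positives = y == c
        if positives.any() and (~positives).any():
            fpr, tpr = roc_points(p[:, c], positives)
            roc[names[c]] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
            auc[names[c]] = trapezoid_auc(fpr, tpr)
            prec, rec, _ = precision_recall_curve(positives, p[:, c])
            pr[names[c]] = {"precision": prec.tolist(), "recall": rec.tolist()}
            ap[names[c]] = float(average_precision_score(positives, p[:, c]))
    onehot = np.eye(k)[y]
    micro_fpr, micro_tpr = roc_points(p.ravel(), onehot.ravel().astype(bool))
    micro_auc = trapezoid_auc(micro_fpr, micro_tpr)
    macro_auc = float(np.mean(list(auc.values()))) if auc else 0.0
    return MetricsReport(
        confusion_matrix=cm, accuracy=accuracy, macro_recall=macro_recall,
        macro_f1=macro_f1, sensitivity=sens, specificity=spec, roc=roc,
        auc=auc, micro_auc=micro_auc, macro_auc=macro_auc, pr=pr,
        average_precision=ap, class_names=names)
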
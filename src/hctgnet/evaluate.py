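"""Confusion matrix and the precision/recall/F1 metric suite.

Metrics follow the standard one-vs-rest definitions read off a 5x5 confusion
matrix in the fixed class order (N, S, V, F, Q): precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 their harmonic mean, with macro (unweighted) and
weighted (support-weighted) aggregates and multiclass accuracy
(total correct / total).  A 0/0 ratio is reported as 0 with an
``undefined`` flag so small synthetic evaluations never divide by zero.

For single-label multiclass data the support-weighted recall equals the
accuracy — an algebraic identity the test suite checks on random inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BeatDataset
from .wfdb_io import CLASSES

N_CLASSES = len(CLASSES)


@dataclass
class EvalReport:
    """Confusion matrix plus per-class / macro / weighted metrics."""

    confusion: np.ndarray                       # [5, 5], rows = true class
    per_class: dict[str, dict[str, float]]      # class -> metric -> value
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    accuracy: float
    n_samples: int
    undefined_classes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["confusion"] = self.confusion.tolist()
        payload["class_order"] = list(CLASSES)
        Path(path).write_text(json.dumps(payload, indent=2))

    def confusion_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.confusion, index=list(CLASSES),
                     columns=list(CLASSES)).to_csv(path)

    def to_table(self) -> str:
        """Human-readable per-class table with the aggregate rows."""
        lines = [f"{'Class':<18}{'Precision':>10}{'Recall':>10}{'F1-Score':>10}"]
        for cls in CLASSES:
            m = self.per_class[cls]
            lines.append(f"{cls:<18}{m['precision']:>10.4f}"
                         f"{m['recall']:>10.4f}{m['f1']:>10.4f}")
        lines.append(f"{'Macro Average':<18}{self.macro_avg['precision']:>10.4f}"
                     f"{self.macro_avg['recall']:>10.4f}"
                     f"{self.macro_avg['f1']:>10.4f}")
        lines.append(f"{'Weighted Average':<18}"
                     f"{self.weighted_avg['precision']:>10.4f}"
                     f"{self.weighted_avg['recall']:>10.4f}"
                     f"{self.weighted_avg['f1']:>10.4f}")
        lines.append(f"{'Accuracy':<18}{'':>10}{'':>10}{self.accuracy:>10.4f}")
        return "\n".join(lines)


def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """5x5 count matrix: entry (i, j) = true class i predicted as class j."""
    y_true = np.asarray(y_true, dtype="U1")
    y_pred = np.asarray(y_pred, dtype="U1")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    lut = {c: i for i, c in enumerate(CLASSES)}
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in lut:
            raise ValueError(f"unknown true label {t!r}")
        if p not in lut:
            raise ValueError(f"unknown predicted label {p!r}")
        cm[lut[t], lut[p]] += 1
    return cm


def class_metrics(confusion: np.ndarray, k: int
                  ) -> tuple[float, float, float, bool]:
    """One-vs-rest (precision, recall, F1, undefined_flag) for class index k."""
    confusion = np.asarray(confusion)
    tp = float(confusion[k, k])
    fp = float(confusion[:, k].sum() - tp)
    fn = float(confusion[k, :].sum() - tp)
    undefined = False
    if tp + fp == 0:
        precision, undefined = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, undefined = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
        undefined = undefined or (tp + fp == 0 and tp + fn == 0)
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1, undefined


def aggregate(per_class: list[tuple[float, float, float]],
              supports: np.ndarray, n_correct: int
              ) -> tuple[dict[str, float], dict[str, float], float]:
    """Macro and support-weighted aggregates plus multiclass accuracy."""
    supports = np.asarray(supports, dtype=float)
    total = supports.sum()
    if total <= 0:
        raise ValueError("total support must be positive")
    arr = np.asarray(per_class, dtype=float)        # [5, 3]
    macro = arr.mean(axis=0)
    weighted = (arr * supports[:, None]).sum(axis=0) / total
    keys = ("precision", "recall", "f1")
    return (dict(zip(keys, macro.tolist())),
            dict(zip(keys, weighted.tolist())),
            n_correct / total)


def report_from_confusion(cm: np.ndarray) -> EvalReport:
    """Assemble the full report from a confusion matrix."""
    cm = np.asarray(cm, dtype=np.int64)
    triples, undefined = [], []
    for k, cls in enumerate(CLASSES):
        p, r, f1, und = class_metrics(cm, k)
        triples.append((p, r, f1))
        if und:
            undefined.append(cls)
    supports = cm.sum(axis=1)
    macro, weighted, accuracy = aggregate(triples, supports,
                                          int(np.trace(cm)))
    per_class = {cls: dict(zip(("precision", "recall", "f1"), t))
                 for cls, t in zip(CLASSES, triples)}
    return EvalReport(confusion=cm, per_class=per_class, macro_avg=macro,
                      weighted_avg=weighted, accuracy=accuracy,
                      n_samples=int(cm.sum()), undefined_classes=undefined)


def macro_f1(y_true, y_pred) -> float:
    """Unweighted mean F1 over the five classes."""
    return report_from_confusion(confusion_matrix(y_true, y_pred)
                                 ).macro_avg["f1"]


def evaluate_model(model, test: BeatDataset, batch_size: int = 512,
                   predict_fn=None) -> EvalReport:
    """Batch inference in evaluation mode followed by the full metric suite.

    Refuses a balanced test set (resampling belongs to training only).
    ``predict_fn`` is a test hook mapping a beat matrix to predicted labels,
    bypassing the model (e.g. to check the metric path with a perfect
    classifier).
    """
    if test.is_balanced():
        raise ValueError(
            "test dataset has been balanced; resampling is applied only to "
            "the training set, so evaluation on it would be biased")
    if len(test) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    if predict_fn is not None:
        y_pred = np.asarray(predict_fn(test.beats), dtype="U1")
    else:
        y_pred = model.predict(test.beats, batch_size=batch_size)
    return report_from_confusion(confusion_matrix(test.labels, y_pred))


def plot_confusion(report: EvalReport, path: str | Path) -> None:
    """Heat-map rendering of the confusion matrix (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    cm = report.confusion
    im = ax.imshow(cm, cmap="Blues")
    ax.set_xticks(range(N_CLASSES), CLASSES)
    ax.set_yticks(range(N_CLASSES), CLASSES)
    ax.set_xlabel("Predicted class")
    ax.set_ylabel("True class")
    thresh = cm.max() / 2 if cm.max() else 0.5
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center",
                    color="white" if cm[i, j] > thresh else "black")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
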
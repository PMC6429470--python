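"""Jackknife (leave-one-out) evaluation and per-class metrics.

The jackknife drops each sample in turn, fits on the remaining n-1 and
predicts the held-out one; the n predictions populate a confusion
matrix (rows = true class, columns = predicted).  Per-class counts are
one-vs-rest, and the metrics are

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FN)(TN+FP))
    Acc = Σ_i TP_i / N

Any metric with a zero denominator is reported as 0.  The MCC uses the
square-rooted denominator of the standard Matthews coefficient (the
product alone would not stay within [−1, 1]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix plus per-class Sn/Sp/MCC and overall accuracy."""

    classes: tuple[str, ...]
    confusion: np.ndarray  # (k, k) ints; rows true, cols predicted
    sn: dict[str, float]
    sp: dict[str, float]
    mcc: dict[str, float]
    overall_acc: float
    n: int

    def to_csv(self) -> str:
        lines = ["class,Sn,Sp,MCC"]
        for c in self.classes:
            lines.append(f"{c},{self.sn[c]:.4f},{self.sp[c]:.4f},{self.mcc[c]:.4f}")
        lines.append(f"Acc,{self.overall_acc:.4f},n={self.n},")
        return "\n".join(lines) + "\n"


def per_class_counts(confusion: np.ndarray, k: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for class index ``k``."""
    confusion = np.asarray(confusion)
    n = int(confusion.sum())
    tp = int(confusion[k, k])
    fn = int(confusion[k, :].sum()) - tp
    fp = int(confusion[:, k].sum()) - tp
    tn = n - tp - fn - fp
    return tp, tn, fp, fn


def metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(Sn, Sp, MCC) with the zero-denominator-means-zero convention."""
    sn = tp / (tp + fn) if tp + fn > 0 else 0.0
    sp = tn / (tn + fp) if tn + fp > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return sn, sp, mcc


def report_from_predictions(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    classes: Sequence[str],
) -> EvaluationReport:
    """Assemble an :class:`EvaluationReport` from paired label lists."""
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predicted_labels, strict=True):
        confusion[index[t], index[p]] += 1
    n = int(confusion.sum())
    sn, sp, mcc = {}, {}, {}
    for c in classes:
        counts = per_class_counts(confusion, index[c])
        sn[c], sp[c], mcc[c] = metrics(*counts)
    acc = float(np.trace(confusion)) / n if n else 0.0
    return EvaluationReport(classes=classes, confusion=confusion, sn=sn, sp=sp, mcc=mcc, overall_acc=acc, n=n)


def jackknife(
    samples: Sequence,
    labels: Sequence[str],
    fit: Callable[[list, list[str]], object],
    predict: Callable[[object, object], str],
    classes: Sequence[str] | None = None,
) -> EvaluationReport:
    """Leave-one-out evaluation of an arbitrary fit/predict pair.

    ``fit`` receives the n-1 training samples and their labels and
    returns a model; ``predict`` receives that model and the held-out
    sample.  Every class must have at least two members, otherwise some
    fold would train without the held-out sample's class.
    """
    samples = list(samples)
    labels = [str(l) for l in labels]
    if len(samples) != len(labels):
        raise ValueError("samples and labels must have equal length")
    if len(samples) < 2:
        raise ValueError("jackknife needs at least two samples")
    if classes is None:
        classes = tuple(dict.fromkeys(labels))
    singletons = [c for c in classes if labels.count(c) < 2]
    if singletons:
        raise ValueError(f"classes with fewer than two samples: {', '.join(singletons)}")
    predictions: list[str] = []
    for i in range(len(samples)):
        train_x = samples[:i] + samples[i + 1 :]
        train_y = labels[:i] + labels[i + 1 :]
        model = fit(train_x, train_y)
        predictions.append(str(predict(model, samples[i])))
    return report_from_predictions(labels, predictions, classes)
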
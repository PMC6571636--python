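"""Multiclass classification quality measures.

Each class is evaluated one-vs-rest through its confusion matrix: sensitivity
(recall), specificity, precision and the Matthews correlation coefficient.
Two global indices summarise a multiclass model symmetrically in the classes:

* NER (non-error rate) — the arithmetic mean of per-class sensitivities, a
  class-balanced alternative to accuracy for unbalanced data;
* AvPr (average precision) — the arithmetic mean of per-class precisions
  (not the ranked-retrieval average precision).

Percentages are reported unrounded; accuracy is computed for completeness but
carries no weight in model selection because it is biased toward the most
numerous class.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "ConfusionMatrix",
    "ClassReport",
    "confusion_for_class",
    "sensitivity",
    "specificity",
    "precision",
    "accuracy",
    "mcc",
    "mean_mcc",
    "global_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """One-vs-rest confusion counts with one class treated as positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"confusion count {name}={v!r} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_for_class(
    y_true: Sequence[str], y_pred: Sequence[str], positive_class: str
) -> ConfusionMatrix:
    """Tally one-vs-rest confusion counts with ``positive_class`` as positive."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    observed = set(y_true) | set(y_pred)
    if positive_class not in observed:
        raise ValueError(f"class {positive_class!r} absent from both label vectors")
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if p == positive_class:
            if t == positive_class:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive_class:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def _ratio_pct(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); returning NaN", stacklevel=3)
        return math.nan
    return 100.0 * num / den


def sensitivity(cm: ConfusionMatrix) -> float:
    """Sn = 100 * TP / (TP + FN), the per-class recall in percent."""
    return _ratio_pct(cm.tp, cm.tp + cm.fn, "sensitivity")


def specificity(cm: ConfusionMatrix) -> float:
    """Sp = 100 * TN / (TN + FP) in percent."""
    return _ratio_pct(cm.tn, cm.tn + cm.fp, "specificity")


def precision(cm: ConfusionMatrix) -> float:
    """Pr = 100 * TP / (TP + FP) in percent."""
    return _ratio_pct(cm.tp, cm.tp + cm.fp, "precision")


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / total in percent. Reported only; never used for selection."""
    return _ratio_pct(cm.tp + cm.tn, cm.total, "accuracy")


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a one-vs-rest confusion matrix.

    Computed in exact integer arithmetic before the final square root. A zero
    factor in the denominator (a degenerate row or column) yields 0.0, the
    standard convention for an uninformative margin.
    """
    num = cm.tp * cm.tn - cm.fp * cm.fn
    den = (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def mean_mcc(y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]) -> float:
    """Arithmetic mean of per-class one-vs-rest MCCs.

    This is the scalar fed into the GA fitness product; the mean is symmetric
    in the classes and robust to class imbalance.
    """
    if not classes:
        raise ValueError("classes must be non-empty")
    return sum(mcc(confusion_for_class(y_true, y_pred, c)) for c in classes) / len(classes)


@dataclass
class ClassReport:
    """Per-class measures plus the global NER / AvPr indices.

    ``per_class`` maps class name -> dict with keys ``tp fp fn tn sn sp pr
    mcc``; percentages may be NaN when a denominator is zero, in which case
    the affected class is excluded from the global mean with a warning.
    """

    classes: tuple[str, ...]
    per_class: dict[str, dict[str, float]]
    ner: float
    avpr: float
    accuracy: float
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "per_class": self.per_class,
            "ner": self.ner,
            "avpr": self.avpr,
            "accuracy": self.accuracy,
            "n": self.n,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [f"{'class':<12} {'TP':>5} {'FP':>5} {'FN':>5} {'TN':>5} "
                 f"{'Sn%':>7} {'Sp%':>7} {'Pr%':>7} {'MCC':>6}"]
        for c in self.classes:
            m = self.per_class[c]
            lines.append(
                f"{c:<12} {m['tp']:>5.0f} {m['fp']:>5.0f} {m['fn']:>5.0f} {m['tn']:>5.0f} "
                f"{m['sn']:>7.1f} {m['sp']:>7.1f} {m['pr']:>7.1f} {m['mcc']:>6.2f}"
            )
        lines.append(f"NER = {self.ner:.2f}%   AvPr = {self.avpr:.2f}%   n = {self.n}")
        return "\n".join(lines)


def _nanmean(values: list[float], what: str) -> float:
    finite = [v for v in values if not math.isnan(v)]
    if len(finite) < len(values):
        warnings.warn(f"{what}: {len(values) - len(finite)} undefined class value(s) "
                      "excluded from the mean", stacklevel=3)
    if not finite:
        return math.nan
    return sum(finite) / len(finite)


def report_from_confusions(confusions: dict[str, ConfusionMatrix]) -> ClassReport:
    """Build a :class:`ClassReport` directly from per-class confusion matrices.

    Useful when only the printed confusion matrices of a model are available
    (no per-compound predictions). Accuracy is taken from the summed diagonal
    of the one-vs-rest matrices and is only meaningful when each matrix covers
    the same evaluation set.
    """
    classes = tuple(confusions)
    per_class: dict[str, dict[str, float]] = {}
    for c, cm in confusions.items():
        per_class[c] = {
            "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
            "sn": sensitivity(cm), "sp": specificity(cm), "pr": precision(cm),
            "mcc": mcc(cm),
        }
    ner = _nanmean([per_class[c]["sn"] for c in classes], "NER")
    avpr = _nanmean([per_class[c]["pr"] for c in classes], "AvPr")
    n = confusions[classes[0]].total if classes else 0
    acc = 100.0 * sum(cm.tp for cm in confusions.values()) / n if n else math.nan
    return ClassReport(classes=classes, per_class=per_class, ner=ner, avpr=avpr,
                       accuracy=acc, n=n)


def global_report(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str] | None = None
) -> ClassReport:
    """Per-class one-vs-rest measures plus NER and AvPr as arithmetic means.

    ``classes`` fixes the evaluation order; by default the sorted union of
    observed labels is used. A class absent from ``y_true`` has undefined
    sensitivity and is excluded from NER with a warning.
    """
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    if len(set(y_true)) < 2:
        raise ValueError("global_report needs at least 2 classes present in y_true")
    confusions = {c: confusion_for_class(y_true, y_pred, c) for c in classes}
    report = report_from_confusions(confusions)
    correct = sum(t == p for t, p in zip(y_true, y_pred))
    report.n = len(y_true)
    report.accuracy = 100.0 * correct / len(y_true) if y_true else math.nan
    return report
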
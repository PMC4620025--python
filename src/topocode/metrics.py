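"""Confusion-count evaluation metrics for phase recognition.

One-vs-rest confusion counts per phase, the derived ratios
(sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
accuracy (TP+TN)/total, F1 = 2·precision·sensitivity/(precision+sensitivity),
error rate = 1 − accuracy), and a multi-class report with per-class
rows, macro averages, and overall accuracy from the confusion diagonal.
Ratios with zero denominators are reported as NaN with an explicit
``undefined`` flag, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synthetic import PHASES

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ClassificationReport",
    "confusion",
    "compute_metrics",
    "multiclass_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Derived proportions in [0, 1]; NaN entries are listed in ``undefined``."""

    sensitivity: float
    specificity: float
    precision: float
    f1: float
    accuracy: float
    error_rate: float
    undefined: tuple[str, ...] = ()


def confusion(
    true: Sequence[str], predicted: Sequence[str], positive: str
) -> ConfusionCounts:
    """One-vs-rest counts treating ``positive`` as the positive class."""
    if len(true) != len(predicted):
        raise ValueError("true and predicted label sequences differ in length")
    t = np.asarray(true) == positive
    p = np.asarray(predicted) == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    undefined: list[str] = []
    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity", undefined)
    spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity", undefined)
    prec = _ratio(counts.tp, counts.tp + counts.fp, "precision", undefined)
    acc = _ratio(counts.tp + counts.tn, counts.total, "accuracy", undefined)
    if math.isnan(prec) or math.isnan(sens) or (prec + sens) == 0:
        undefined.append("f1")
        f1 = math.nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    err = 1.0 - acc if not math.isnan(acc) else math.nan
    if math.isnan(err) and "accuracy" not in undefined:
        undefined.append("error_rate")
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
        accuracy=acc,
        error_rate=err,
        undefined=tuple(undefined),
    )


@dataclass(frozen=True)
class ClassificationReport:
    """Per-class one-vs-rest metrics plus macro averages and the overall
    multi-class accuracy/error rate from the confusion diagonal."""

    per_class: dict[str, MetricsReport]
    macro: MetricsReport
    accuracy: float
    error_rate: float
    n_samples: int


def multiclass_report(
    true: Sequence[str], predicted: Sequence[str]
) -> ClassificationReport:
    if len(true) != len(predicted):
        raise ValueError("true and predicted label sequences differ in length")
    if len(true) == 0:
        raise ValueError("cannot evaluate an empty sample set")
    per_class = {
        phase: compute_metrics(confusion(true, predicted, phase)) for phase in PHASES
    }

    def _macro(attr: str) -> float:
        vals = [getattr(r, attr) for r in per_class.values()]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    macro = MetricsReport(
        sensitivity=_macro("sensitivity"),
        specificity=_macro("specificity"),
        precision=_macro("precision"),
        f1=_macro("f1"),
        accuracy=_macro("accuracy"),
        error_rate=_macro("error_rate"),
    )
    acc = float(np.mean(np.asarray(true) == np.asarray(predicted)))
    return ClassificationReport(
        per_class=per_class,
        macro=macro,
        accuracy=acc,
        error_rate=1.0 - acc,
        n_samples=len(true),
    )
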
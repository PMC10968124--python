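"""Run-level statistics and confusion-matrix classification indices.

Across repeated optimizer runs the standard summary is the mean best fitness,
the mean accuracy (1 - error) of the best subsets, and the mean feature
selection ratio (subset size / D).  Classifier quality is reported with the
five confusion-matrix indices TPR (recall), PPV (precision), TNR
(specificity), NPV and ACC; indices with a zero denominator are reported as
undefined (None), never silently zero.  Multi-class problems are handled
one-vs-rest per class and macro-averaged over the defined values; two-class
problems reduce to the plain binary definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .optimizer import RunResult

__all__ = [
    "ConfusionCounts",
    "ConfusionMetrics",
    "ExperimentSummary",
    "confusion_metrics",
    "confusion_from_labels",
    "classification_indices",
    "run_statistics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts must total at least 1")


@dataclass(frozen=True)
class ConfusionMetrics:
    """The five classification indices; None marks an undefined (0/0) index."""

    tpr: float | None
    ppv: float | None
    tnr: float | None
    npv: float | None
    acc: float

    def as_tuple(self):
        return (self.tpr, self.ppv, self.tnr, self.npv, self.acc)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(counts: ConfusionCounts) -> ConfusionMetrics:
    """TPR, PPV, TNR, NPV and ACC from binary confusion counts."""
    return ConfusionMetrics(
        tpr=_ratio(counts.tp, counts.tp + counts.fn),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        tnr=_ratio(counts.tn, counts.tn + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
        acc=(counts.tp + counts.tn) / (counts.tp + counts.tn + counts.fp + counts.fn),
    )


def confusion_from_labels(y_true, y_pred, positive) -> ConfusionCounts:
    """Binary confusion counts treating ``positive`` as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must share a shape")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def classification_indices(y_true, y_pred, positive=None) -> ConfusionMetrics:
    """Classification indices from predicted labels.

    With two classes the indices are the plain binary ones (positive class =
    ``positive``, defaulting to the last class in sorted order).  With more
    classes each index is computed one-vs-rest per class and macro-averaged
    over the classes where it is defined.
    """
    y_true = np.asarray(y_true)
    classes = np.unique(y_true)
    if len(classes) == 2 or positive is not None:
        pos = positive if positive is not None else classes[-1]
        return confusion_metrics(confusion_from_labels(y_true, y_pred, pos))
    per_class = [confusion_metrics(confusion_from_labels(y_true, y_pred, c))
                 for c in classes]

    def macro(vals):
        defined = [v for v in vals if v is not None]
        return float(np.mean(defined)) if defined else None

    return ConfusionMetrics(
        tpr=macro([m.tpr for m in per_class]),
        ppv=macro([m.ppv for m in per_class]),
        tnr=macro([m.tnr for m in per_class]),
        npv=macro([m.npv for m in per_class]),
        acc=float(np.mean(np.asarray(y_true) == np.asarray(y_pred))),
    )


@dataclass
class ExperimentSummary:
    mean_fitness: float
    mean_accuracy: float
    mean_subset_ratio: float
    n_runs: int
    per_run: list


def run_statistics(results: Sequence[RunResult], total_features: int) -> ExperimentSummary:
    """Mean fitness, mean accuracy and mean feature-selection ratio over runs."""
    if len(results) == 0:
        raise ValueError("need at least one run")
    if total_features < 1:
        raise ValueError("total_features must be >= 1")
    return ExperimentSummary(
        mean_fitness=float(np.mean([r.best_fitness for r in results])),
        mean_accuracy=float(np.mean([1.0 - r.best_error for r in results])),
        mean_subset_ratio=float(np.mean([r.subset_size / total_features
                                         for r in results])),
        n_runs=len(results),
        per_run=list(results),
    )
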
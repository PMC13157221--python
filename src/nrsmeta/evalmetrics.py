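"""Evaluation of read classification against simulation ground truth.

Micro-averaged species-level precision/recall/F1 (TP/FP/FN counts pooled
across labels — and across grid cells — before the ratios are formed), plus
threshold-free metrics on the per-read best-NRS score: AUPRC by the
step-wise precision-at-recall sum (the conservative convention for
imbalanced data) and AUC-ROC by trapezoidal integration with ties grouped.

Convention for unclassified reads: they contribute a false negative at
their true label and no false positive anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .similarity import UNCLASSIFIED, ReadAssignment

__all__ = [
    "LabelCounts",
    "EvalResult",
    "confusion",
    "pr_curve_auprc",
    "roc_auc",
    "evaluate_run",
]


@dataclass
class LabelCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


@dataclass
class EvalResult:
    """Pooled micro-averaged counts and derived metrics."""

    per_label: dict[str, LabelCounts]
    tp: int
    fp: int
    fn: int
    auprc: float | None = None
    auroc: float | None = None

    @property
    def precision(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def confusion(
    assignments: Mapping[str, str] | Sequence[ReadAssignment],
    truth: Mapping[str, str],
) -> EvalResult:
    """Per-label and micro-pooled TP/FP/FN from read assignments.

    ``assignments`` maps read_id to predicted label (or the unclassified
    marker); ``truth`` maps read_id to the true label.  A correct prediction
    is a TP; a wrong one charges an FP to the predicted label and an FN to
    the true label; an unclassified read is an FN only.  Every assigned
    read_id must be present in truth.
    """
    if not isinstance(assignments, Mapping):
        assignments = {a.read_id: a.best_reference for a in assignments}
    per_label: dict[str, LabelCounts] = {}

    def bucket(label: str) -> LabelCounts:
        if label not in per_label:
            per_label[label] = LabelCounts()
        return per_label[label]

    tp = fp = fn = 0
    for read_id, predicted in assignments.items():
        if read_id not in truth:
            raise KeyError(f"read {read_id!r} absent from ground truth")
        actual = truth[read_id]
        if predicted == actual:
            bucket(actual).tp += 1
            tp += 1
        elif predicted == UNCLASSIFIED:
            bucket(actual).fn += 1
            fn += 1
        else:
            bucket(predicted).fp += 1
            bucket(actual).fn += 1
            fp += 1
            fn += 1
    return EvalResult(per_label=per_label, tp=tp, fp=fp, fn=fn)


def pr_curve_auprc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the precision-recall curve.

    Thresholds sweep the distinct scores descending (ties grouped); the area
    is the step-wise sum over recall increments of the precision attained,
    sum_i (R_i - R_{i-1}) * P_i, without interpolation.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.size == 0 or not labels.any():
        raise ValueError("AUPRC needs at least one positive example")
    return float(average_precision_score(labels, scores))


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve (trapezoidal, ties grouped).

    Equivalent to the rank-sum estimator: the probability that a random
    positive outscores a random negative, with ties worth half.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if not labels.any() or labels.all():
        raise ValueError("AUROC needs at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def evaluate_run(
    assignments: Sequence[ReadAssignment],
    truth: Mapping[str, str],
) -> EvalResult:
    """Confusion counts plus AUPRC/AUROC over the best-NRS scores.

    The score of each read is its best NRS; the binary label is whether the
    assignment is correct.  Threshold-free metrics are left unset when the
    correctness labels are degenerate (all correct or all wrong).
    """
    result = confusion(assignments, truth)
    scores = np.array([a.best_nrs for a in assignments], dtype=np.float64)
    correct = np.array(
        [a.best_reference == truth[a.read_id] for a in assignments], dtype=bool
    )
    if correct.any():
        result.auprc = pr_curve_auprc(scores, correct)
    if correct.any() and not correct.all():
        result.auroc = roc_auc(scores, correct)
    return result
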
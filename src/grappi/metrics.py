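"""Ranking and classification metrics for scored model sets.

Ranking metrics operate on scores where higher means better.  Ties in a
ranking are broken by a stable sort on model id, so top-N metrics are
deterministic.  Division-by-zero cells of the confusion matrix are
reported as NaN (undefined), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; ties handled by rank averaging
    (equivalent to the Mann-Whitney U statistic)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def rank_by_score(ids, scores) -> list[int]:
    """Indices sorted by descending score, ties broken by ascending id."""
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return order


def hit_rate(ranked_labels, top_n: int) -> float:
    """Percentage of all positives found in the top N of a ranking."""
    labels = np.asarray(ranked_labels)
    total = int(labels.sum())
    if total == 0:
        raise ValueError("hit rate undefined with zero positives")
    return 100.0 * int(labels[:top_n].sum()) / total


def success_rate(per_complex_ranked_labels: dict, top_n: int) -> float:
    """Percentage of complexes with at least one positive in the top N."""
    if not per_complex_ranked_labels:
        raise ValueError("no complexes")
    hits = sum(1 for labels in per_complex_ranked_labels.values()
               if np.asarray(labels)[:top_n].sum() > 0)
    return 100.0 * hits / len(per_complex_ranked_labels)


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    tp: int
    fp: int
    tn: int
    fn: int


def classification_report(predictions, labels) -> ClassificationReport:
    """Confusion-matrix ratios for binary predictions (1 = positive)."""
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return ClassificationReport(
        accuracy=ratio(tp + tn, tp + tn + fp + fn),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def spearman_rho(scores, targets) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    rho, _ = spearmanr(np.asarray(scores, dtype=float),
                       np.asarray(targets, dtype=float))
    return float(rho)


def averaged_roc_curve(per_complex: dict, fpr_grid=None):
    """TPR averaged across complexes on a fixed FPR grid.

    ``per_complex`` maps complex id to (scores, labels).  Used for
    multi-complex ROC summaries where each complex contributes one curve.
    """
    from sklearn.metrics import roc_curve
    if fpr_grid is None:
        fpr_grid = np.linspace(0, 1, 101)
    tprs = []
    for scores, labels in per_complex.values():
        fpr, tpr, _ = roc_curve(labels, scores)
        tprs.append(np.interp(fpr_grid, fpr, tpr))
    return fpr_grid, np.mean(tprs, axis=0)
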
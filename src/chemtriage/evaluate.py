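"""Validation machinery: splits, confusion counts, MCC, ROC/AUC, top-k ranking.

Conventions
-----------
* The positive class (label 1) is the "corpus-like" class.
* MCC uses the zero-denominator convention: if any of the four marginal
  factors is zero, MCC is reported as 0.
* Sensitivity/specificity are reported as NaN (not 0) when their denominator
  is empty.
* AUC is the tie-aware rank statistic — the probability that a random
  positive outscores a random negative, ties counted 1/2 — which equals
  trapezoidal integration of the tie-aware ROC curve.
* Ranking ties are broken by doc_id (or index) so every ordering is
  deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def stratified_split(
    labels: Sequence[int], test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified holdout split.

    Per class, round(class_size * test_fraction) items go to the test side
    after a seeded within-class shuffle. Returns (train_idx, test_idx).
    """
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must be in (0, 1)")
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("both classes must be present to split")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if idx.size < 2:
            raise ValidationError(f"class {c} has fewer than 2 members")
        rng.shuffle(idx)
        n_test = int(round(idx.size * test_fraction))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def confusion(predicted: Sequence[int], true: Sequence[int]) -> ConfusionMatrix:
    pred = np.asarray(predicted)
    y = np.asarray(true)
    if pred.shape != y.shape:
        raise ValidationError("predicted and true label lengths differ")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def sensitivity_specificity(cm: ConfusionMatrix) -> tuple[float, float]:
    """TP/(TP+FN) and TN/(TN+FP); NaN where the denominator is zero."""
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else math.nan
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else math.nan
    return sens, spec


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient with the 0-on-degenerate convention."""
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, list[tuple[float, float]]]:
    """Tie-aware AUC and the ROC step curve.

    AUC is computed from mid-ranks (Mann-Whitney statistic); the curve sweeps
    every distinct score threshold from high to low and runs from (0,0) to
    (1,1), tied scores moving diagonally in one step.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC/AUC needs both classes present")
    ranks = rankdata(s)  # mid-ranks for ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            tp += int(y_sorted[j] == 1)
            fp += int(y_sorted[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return float(auc), points


def best_mcc_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Score cut maximizing MCC under 'positive iff score >= threshold'.

    Candidates are the distinct observed scores; on ties the lowest winning
    threshold is returned; degenerate inputs fall back to 0.0.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if np.unique(s).size <= 1 or np.unique(y).size < 2:
        return 0.0
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # last position of each distinct score in the descending order
    boundaries = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    cum_tp = np.cumsum(y_sorted == 1)
    n_pos = int(cum_tp[-1])
    n_neg = len(y) - n_pos
    tp = cum_tp[boundaries].astype(float)
    k = boundaries + 1.0
    fp = k - tp
    fn = n_pos - tp
    tn = n_neg - fp
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(denom > 0, (tp * tn - fp * fn) / denom, 0.0)
    best = np.flatnonzero(m == m.max())[-1]  # lowest threshold among ties
    return float(s_sorted[boundaries[best]]) if m.max() > 0 else 0.0


def rank_order(
    scores: Sequence[float], tie_keys: Sequence[str] | None = None
) -> np.ndarray:
    """Indices sorted by descending score, ties broken by ascending key."""
    s = np.asarray(scores, dtype=float)
    if tie_keys is None:
        return np.argsort(-s, kind="mergesort")
    keyed = sorted(range(len(s)), key=lambda i: (-s[i], tie_keys[i]))
    return np.asarray(keyed, dtype=np.int64)


def top_fraction_errors(
    scores: Sequence[float],
    labels: Sequence[int],
    fraction: float,
    doc_ids: Sequence[str] | None = None,
) -> tuple[int, int, int]:
    """Error counts in the top slice of the score ranking.

    Returns (n_top, n_fp, n_tp) with n_top = floor(fraction * N); n_fp is the
    number of true negatives and n_tp the number of true positives in the
    slice (they sum to n_top).
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    y = np.asarray(labels)
    order = rank_order(scores, doc_ids)
    n_top = int(math.floor(fraction * len(y)))
    top = y[order[:n_top]]
    n_tp = int(np.sum(top == 1))
    return n_top, n_top - n_tp, n_tp


@dataclass
class EvalReport:
    """Full validation summary for one model on one labeled set."""

    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    mcc: float
    auc: float
    roc_points: list[tuple[float, float]]
    topk: list[tuple[float, int, int, int]]  # (fraction, n_top, n_fp, n_tp)
    validation_set: str = "holdout"

    def to_dict(self) -> dict:
        return {
            "validation_set": self.validation_set,
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "fn": self.confusion.fn,
            },
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "auc": self.auc,
            "roc_points": self.roc_points,
            "topk": [
                {"fraction": f, "n_top": nt, "n_fp": nf, "n_tp": np_}
                for f, nt, nf, np_ in self.topk
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary_row(self, method: str) -> str:
        """One summary-table line: method, AUC, MCC, sensitivity, specificity."""
        return "\t".join(
            [
                f"{method}/{self.validation_set}",
                f"{self.auc:.2f}",
                f"{self.mcc:.2f}",
                f"{self.sensitivity:.2f}",
                f"{self.specificity:.2f}",
            ]
        )

    def roc_tsv(self) -> str:
        lines = ["fpr\ttpr"]
        lines += [f"{fpr!r}\t{tpr!r}" for fpr, tpr in self.roc_points]
        return "\n".join(lines) + "\n"


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
    topk_fractions: Sequence[float] = (0.05, 0.10),
    doc_ids: Sequence[str] | None = None,
    validation_set: str = "holdout",
) -> EvalReport:
    """Assemble an EvalReport from raw scores, labels and a decision cut."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred = (s >= threshold).astype(int)
    cm = confusion(pred, y)
    sens, spec = sensitivity_specificity(cm)
    auc, points = roc_auc(s, y)
    topk = [
        (f, *top_fraction_errors(s, y, f, doc_ids)) for f in topk_fractions
    ]
    return EvalReport(
        confusion=cm,
        sensitivity=sens,
        specificity=spec,
        mcc=mcc(cm),
        auc=auc,
        roc_points=points,
        topk=topk,
        validation_set=validation_set,
    )


def evaluate_model(
    model,
    matrix,
    topk_fractions: Sequence[float] = (0.05, 0.10),
    mode: str = "holdout",
) -> EvalReport:
    """Score a labeled matrix with a trained model and summarize.

    ``mode="oob"`` evaluates a ForestModel on its out-of-bag scores (the
    matrix must then be the training matrix, in training row order).
    """
    if matrix.labels is None:
        raise ValidationError("matrix has no labels to evaluate against")
    if mode == "oob":
        scores = model.oob_scores
        if scores is None:
            raise ValidationError("model has no out-of-bag scores")
        mask = ~np.isnan(scores)
        return evaluate_scores(
            scores[mask],
            matrix.labels[mask],
            threshold=model.threshold,
            topk_fractions=topk_fractions,
            doc_ids=[matrix.doc_ids[i] for i in np.flatnonzero(mask)],
            validation_set="oob",
        )
    scores = model.decision_scores(matrix)
    return evaluate_scores(
        scores,
        matrix.labels,
        threshold=model.threshold,
        topk_fractions=topk_fractions,
        doc_ids=matrix.doc_ids,
        validation_set=mode,
    )
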
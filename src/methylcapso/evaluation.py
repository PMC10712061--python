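"""Confusion-matrix statistics: SN, SP, ACC, MCC and the rank-statistic AUC.

SN, SP and ACC are reported as percentages; MCC is the Matthews correlation
coefficient in [-1, 1]; AUC is computed from the rank-sum formula

    AUC = (sum of positive ranks - n_pos (n_pos + 1) / 2) / (n_pos * n_neg)

with tied scores receiving average ranks, which makes the formula coincide
exactly with the all-pairs Mann-Whitney statistic (half credit for ties).
Any metric whose denominator vanishes is reported as 0 and flagged
degenerate rather than raising, so cross-dataset sweeps survive one-sided
folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion_counts",
    "classification_metrics",
    "auc_rank",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class EvaluationReport:
    """Five-metric classification report at a fixed decision threshold."""

    counts: ConfusionCounts
    sn_pct: float
    sp_pct: float
    acc_pct: float
    mcc: float
    auc: float
    threshold: float
    degenerate_flags: tuple[str, ...] = ()
    tag: str | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.TP,
            "fp": self.counts.FP,
            "tn": self.counts.TN,
            "fn": self.counts.FN,
            "sn_pct": self.sn_pct,
            "sp_pct": self.sp_pct,
            "acc_pct": self.acc_pct,
            "mcc": self.mcc,
            "auc": self.auc,
            "threshold": self.threshold,
            "degenerate_flags": list(self.degenerate_flags),
            "tag": self.tag,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _check_inputs(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1 or labels.size < 1:
        raise ValueError("labels and scores must be equal-length 1-D collections")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return labels.astype(int), scores


def confusion_counts(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion matrix; a score equal to the threshold is positive."""
    labels, scores = _check_inputs(labels, scores)
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def classification_metrics(counts: ConfusionCounts) -> dict:
    """SN, SP, ACC (percent) and MCC from confusion counts.

    A metric with a zero denominator is reported as 0 and named in
    ``degenerate_flags``.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    flags = []

    if tp + fn > 0:
        sn = 100.0 * tp / (tp + fn)
    else:
        sn, flags = 0.0, flags + ["sn"]
    if tn + fp > 0:
        sp = 100.0 * tn / (tn + fp)
    else:
        sp, flags = 0.0, flags + ["sp"]
    acc = 100.0 * (tp + tn) / counts.total

    mcc_den = (
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if mcc_den > 0:
        mcc = (float(tp) * tn - float(fp) * fn) / np.sqrt(mcc_den)
    else:
        mcc, flags = 0.0, flags + ["mcc"]
    return {
        "sn_pct": sn,
        "sp_pct": sp,
        "acc_pct": acc,
        "mcc": mcc,
        "degenerate_flags": tuple(flags),
    }


def auc_rank(labels, scores) -> float:
    """Rank-statistic AUC with average ranks for ties.

    Requires at least one positive and one negative.  Equals the fraction of
    (positive, negative) pairs ranked correctly, counting ties as half.
    """
    labels, scores = _check_inputs(labels, scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative label")
    ranks = rankdata(scores, method="average")
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(labels, scores, threshold: float = 0.5, tag: str | None = None) -> EvaluationReport:
    """Full report: confusion counts, SN/SP/ACC/MCC and rank AUC.

    AUC for a single-class input is reported as 0 with an ``auc`` degenerate
    flag instead of raising, so sweeps over many folds never abort.
    """
    counts = confusion_counts(labels, scores, threshold)
    metrics = classification_metrics(counts)
    flags = list(metrics["degenerate_flags"])
    try:
        auc = auc_rank(labels, scores)
    except ValueError:
        auc, flags = 0.0, flags + ["auc"]
    return EvaluationReport(
        counts=counts,
        sn_pct=metrics["sn_pct"],
        sp_pct=metrics["sp_pct"],
        acc_pct=metrics["acc_pct"],
        mcc=metrics["mcc"],
        auc=auc,
        threshold=threshold,
        degenerate_flags=tuple(flags),
        tag=tag,
    )
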
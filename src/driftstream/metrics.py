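"""Evaluation metrics: accuracy, sensitivity, specificity, F1 and rank AUC.

Multiclass problems are handled one-vs-rest (OVR): ``micro_ovr`` pools
TP/TN/FP/FN counts across classes before applying the formulas (which makes
pooled sensitivity identical to accuracy), ``macro_ovr`` averages the
per-class values, and ``binary`` reads the counts of class 1 as the positive
class.  AUC uses the rank-sum (Mann-Whitney) form with average ranks on ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import FormatError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "acc_sen_spe_f1",
    "auc_rank",
    "multiclass_auc",
    "compute_report",
]

logger = logging.getLogger(__name__)

MICRO_OVR = "micro_ovr"
MACRO_OVR = "macro_ovr"
BINARY = "binary"


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest counts; arrays have one entry per class."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    total: int

    @property
    def n_classes(self) -> int:
        return self.tp.shape[0]

    @property
    def n_correct(self) -> int:
        return int(self.tp.sum())


def confusion(
    true_labels: np.ndarray, pred_labels: np.ndarray, n_classes: int
) -> ConfusionCounts:
    """Tabulate per-class one-vs-rest TP/TN/FP/FN."""
    true_labels = np.asarray(true_labels, dtype=int)
    pred_labels = np.asarray(pred_labels, dtype=int)
    if true_labels.shape != pred_labels.shape:
        raise FormatError(
            f"label vectors differ in length: {true_labels.shape} vs {pred_labels.shape}"
        )
    for name, arr in (("true", true_labels), ("pred", pred_labels)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(
                f"{name} labels out of range [0, {n_classes}): "
                f"[{arr.min()}, {arr.max()}]"
            )
    total = true_labels.size
    classes = np.arange(n_classes)
    is_true = true_labels[:, None] == classes
    is_pred = pred_labels[:, None] == classes
    tp = (is_true & is_pred).sum(axis=0)
    fp = (~is_true & is_pred).sum(axis=0)
    fn = (is_true & ~is_pred).sum(axis=0)
    tn = total - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, total=total)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def _single(tp: float, tn: float, fp: float, fn: float) -> tuple[float, float, float, float]:
    acc = _safe_div(tp + tn, tp + tn + fp + fn)
    sen = _safe_div(tp, tp + fn)
    spe = _safe_div(tn, fp + tn)
    precision = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * precision * sen, precision + sen)
    return acc, sen, spe, f1


def acc_sen_spe_f1(
    counts: ConfusionCounts, averaging: str = MICRO_OVR
) -> tuple[float, float, float, float]:
    """(ACC, SEN, SPE, F1) under the requested averaging scheme.

    ACC is always the plain fraction of correctly classified samples.
    Zero-denominator terms are defined as 0.
    """
    acc = _safe_div(counts.n_correct, counts.total)
    if averaging == BINARY:
        if counts.n_classes != 2:
            raise ValueError("binary averaging requires exactly 2 classes")
        _, sen, spe, f1 = _single(
            counts.tp[1], counts.tn[1], counts.fp[1], counts.fn[1]
        )
        return acc, sen, spe, f1
    if averaging == MICRO_OVR:
        _, sen, spe, f1 = _single(
            counts.tp.sum(), counts.tn.sum(), counts.fp.sum(), counts.fn.sum()
        )
        return acc, sen, spe, f1
    if averaging == MACRO_OVR:
        per = np.array(
            [
                _single(counts.tp[k], counts.tn[k], counts.fp[k], counts.fn[k])
                for k in range(counts.n_classes)
            ]
        )
        _, sen, spe, f1 = per.mean(axis=0)
        return acc, float(sen), float(spe), float(f1)
    raise ValueError(f"unknown averaging {averaging!r}")


def auc_rank(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """Rank-sum AUC: (sum of positive ranks - M(1+M)/2) / (M*N).

    Ranks are ascending with average ranks on ties; M positives, N negatives.
    """
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if scores.shape != is_positive.shape:
        raise FormatError("scores and is_positive differ in length")
    M = int(is_positive.sum())
    N = int((~is_positive).sum())
    if M == 0 or N == 0:
        raise ValueError("need at least one positive and one negative sample")
    ranks = rankdata(scores, method="average")
    return float((ranks[is_positive].sum() - M * (1 + M) / 2) / (M * N))


def multiclass_auc(
    prob_matrix: np.ndarray, true_labels: np.ndarray, averaging: str = MACRO_OVR
) -> float:
    """One-vs-rest AUC per class on that class's probability column.

    ``macro_ovr`` (default) averages the per-class AUCs; ``micro_ovr`` pools
    all (score, indicator) pairs into a single ranking.  Classes absent from
    ``true_labels`` are skipped with a logged warning.
    """
    prob_matrix = np.asarray(prob_matrix, dtype=float)
    true_labels = np.asarray(true_labels, dtype=int)
    n_classes = prob_matrix.shape[1]
    present = [k for k in range(n_classes) if np.any(true_labels == k)]
    if len(present) < 2:
        raise ValueError("need at least 2 classes present in true_labels")
    for k in range(n_classes):
        if k not in present:
            logger.warning("class %d absent from true labels; skipped in AUC", k)
    if averaging == MICRO_OVR:
        scores = np.concatenate([prob_matrix[:, k] for k in present])
        flags = np.concatenate([true_labels == k for k in present])
        return auc_rank(scores, flags)
    if averaging == MACRO_OVR:
        return float(
            np.mean([auc_rank(prob_matrix[:, k], true_labels == k) for k in present])
        )
    raise ValueError(f"unknown averaging {averaging!r}")


@dataclass(frozen=True)
class MetricReport:
    """One row of evaluation output; all values in [0, 1]."""

    acc: float
    sen: float
    spe: float
    f1: float
    auc: float
    averaging: str

    def to_record(self) -> dict:
        return {
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "f1": self.f1,
            "auc": self.auc,
            "averaging": self.averaging,
        }


def compute_report(
    true_labels: np.ndarray,
    pred_labels: np.ndarray,
    prob_matrix: np.ndarray,
    n_classes: int,
    averaging: str = MICRO_OVR,
) -> MetricReport:
    """Confusion counts + AUC in one call; AUC falls back to 0.5 when only one
    class is present in ``true_labels`` (undefined ranking)."""
    counts = confusion(true_labels, pred_labels, n_classes)
    acc, sen, spe, f1 = acc_sen_spe_f1(counts, averaging)
    try:
        auc_avg = MACRO_OVR if averaging == BINARY else averaging
        auc = multiclass_auc(prob_matrix, true_labels, auc_avg)
    except ValueError:
        auc = 0.5
    return MetricReport(acc=acc, sen=sen, spe=spe, f1=f1, auc=auc, averaging=averaging)
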
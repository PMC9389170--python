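"""Per-segment metrics and per-recording apnea diagnosis.

Per segment: accuracy, recall (sensitivity), specificity, precision and F1
from the confusion counts with SA as the positive class, plus ROC/AUC.

Per recording: the apnea-hypopnea index AHI = 60 * N / T from N predicted SA
minutes out of T evaluated minutes, with the clinical SA call at AHI > 5
(strict).  Across a cohort, predicted AHI is compared to annotation-derived
AHI by mean absolute error and the Pearson correlation coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score

from .model import Model, model_forward
from .preprocessing import WindowSet

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "RecordingResult",
    "CohortEvaluation",
    "SegmentEvaluation",
    "confusion_metrics",
    "roc_auc",
    "evaluate_recording",
    "cohort_mae_corr",
    "evaluate_per_segment",
    "evaluate_recordings",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """SA = positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    recall: float
    specificity: float
    precision: float
    f1: float

    def as_percent(self) -> dict:
        return {k: round(100.0 * v, 2) for k, v in vars(self).items()}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, recall, specificity, precision and F1; undefined ratios are NaN."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from empty counts")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    accuracy = (c.tp + c.tn) / c.total
    f1 = (
        2 * precision * recall / (precision + recall)
        if np.isfinite(precision) and np.isfinite(recall) and (precision + recall) > 0
        else float("nan")
    )
    return Metrics(accuracy, recall, specificity, precision, f1)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = P(random SA segment outscores a random normal one), ties at 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class RecordingResult:
    """Per-recording diagnosis from the per-minute predictions."""

    record_id: str
    minute_predictions: np.ndarray
    n_sa: int
    t_total: int
    ahi_pred: float
    diagnosis: str  # "SA" or "normal"


def evaluate_recording(minute_predictions: np.ndarray, record_id: str = "") -> RecordingResult:
    """AHI = 60 * N / T over the evaluated minutes; diagnosis SA iff AHI > 5 (strict)."""
    pred = np.asarray(minute_predictions, dtype=int)
    if pred.size == 0:
        raise ValueError("need at least one evaluated minute")
    if not np.isin(pred, (0, 1)).all():
        raise ValueError("minute predictions must be 0/1")
    n, t = int(pred.sum()), int(pred.size)
    ahi = 60.0 * n / t
    return RecordingResult(
        record_id=record_id,
        minute_predictions=pred,
        n_sa=n,
        t_total=t,
        ahi_pred=ahi,
        diagnosis="SA" if ahi > 5.0 else "normal",
    )


@dataclass
class CohortEvaluation:
    pairs: list  # (ahi_pred, ahi_true)
    mae: float
    corr: float


def cohort_mae_corr(pairs) -> CohortEvaluation:
    """Mean absolute AHI error and Pearson correlation across recordings."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be a non-empty list of (ahi_pred, ahi_true)")
    pred, true = arr[:, 0], arr[:, 1]
    mae = float(np.mean(np.abs(pred - true)))
    if arr.shape[0] < 2 or np.std(pred) == 0 or np.std(true) == 0:
        warnings.warn("Pearson correlation undefined (fewer than 2 recordings or zero variance)")
        corr = float("nan")
    else:
        corr = float(pearsonr(pred, true)[0])
    return CohortEvaluation(pairs=[tuple(p) for p in arr], mae=mae, corr=corr)


@dataclass
class SegmentEvaluation:
    counts: ConfusionCounts
    metrics: Metrics
    auc: float
    probabilities: np.ndarray = field(repr=False, default=None)
    predictions: np.ndarray = field(repr=False, default=None)


def evaluate_per_segment(model: Model, ws: WindowSet) -> SegmentEvaluation:
    """Classify every window (argmax of the softmax pair) and aggregate metrics."""
    if len(ws) == 0:
        raise ValueError("cannot evaluate an empty window set")
    probs = model_forward(model, ws.X)
    p_sa = probs[:, 1]
    pred = probs.argmax(axis=1)
    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (ws.y == 1))),
        fp=int(np.sum((pred == 1) & (ws.y == 0))),
        tn=int(np.sum((pred == 0) & (ws.y == 0))),
        fn=int(np.sum((pred == 0) & (ws.y == 1))),
    )
    try:
        auc = roc_auc(p_sa, ws.y)
    except ValueError:
        auc = float("nan")
    return SegmentEvaluation(
        counts=counts,
        metrics=confusion_metrics(counts),
        auc=auc,
        probabilities=probs,
        predictions=pred,
    )


def evaluate_recordings(model: Model, ws: WindowSet) -> tuple[list[RecordingResult], CohortEvaluation]:
    """Group windows by recording, derive predicted and annotation AHI per record.

    Both AHIs are computed over the minutes that survived preprocessing, so
    the comparison is like for like.
    """
    if not ws.record_ids:
        raise ValueError("window set carries no record ids")
    probs = model_forward(model, ws.X)
    pred = probs.argmax(axis=1)
    results, pairs = [], []
    for rid in dict.fromkeys(ws.record_ids):  # preserve first-seen order
        sel = np.array([r == rid for r in ws.record_ids])
        res = evaluate_recording(pred[sel], record_id=rid)
        ahi_true = 60.0 * float(ws.y[sel].sum()) / float(sel.sum())
        results.append(res)
        pairs.append((res.ahi_pred, ahi_true))
    return results, cohort_mae_corr(pairs)
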
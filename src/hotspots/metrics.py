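"""Binary-classification evaluation statistics for hot-spot prediction.

Hot-Spots (HS) are the positive class throughout: TP counts correctly
classified HS, TN correctly classified NS.  Ratios with a zero denominator
are reported as NaN together with a human-readable reason instead of
raising, so that degenerate cross-validation folds (e.g. a fold without a
single HS) do not abort a benchmark run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

POSITIVE = "HS"
NEGATIVE = "NS"
VALID_LABELS = frozenset({POSITIVE, NEGATIVE})


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    tpr: float
    tnr: float
    ppv: float
    npv: float
    fdr: float
    fnr: float
    f1: float
    mcc: float
    auroc: float = math.nan
    reasons: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "AUROC": self.auroc, "Accuracy": self.accuracy, "TPR": self.tpr,
            "TNR": self.tnr, "PPV": self.ppv, "NPV": self.npv,
            "FDR": self.fdr, "FNR": self.fnr, "F1": self.f1, "MCC": self.mcc,
        }


def _as_labels(values: Sequence) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    bad = [v for v in arr if v not in VALID_LABELS]
    if bad:
        raise ValueError(
            f"labels must be 'HS' or 'NS'; got {sorted(set(map(str, bad)))}"
        )
    return arr


def confusion(pred: Sequence, truth: Sequence) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with HS as the positive class."""
    p, t = _as_labels(pred), _as_labels(truth)
    if len(p) != len(t):
        raise ValueError(f"length mismatch: {len(p)} predictions vs {len(t)} truths")
    if len(p) == 0:
        raise ValueError("empty label vectors")
    tp = int(np.sum((p == POSITIVE) & (t == POSITIVE)))
    tn = int(np.sum((p == NEGATIVE) & (t == NEGATIVE)))
    fp = int(np.sum((p == POSITIVE) & (t == NEGATIVE)))
    fn = int(np.sum((p == NEGATIVE) & (t == POSITIVE)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float, name: str, reasons: dict) -> float:
    if den == 0:
        reasons[name] = f"undefined: zero denominator in {name}"
        return math.nan
    return num / den


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """Evaluate the standard confusion-matrix statistics.

    Accuracy, TPR (sensitivity/recall), TNR (specificity), PPV (precision),
    NPV, FDR = 1 - PPV, FNR = 1 - TPR, F1 = 2TP/(2TP+FP+FN) and Matthews
    correlation.  NPV is computed as TN/(TN+FN), the standard form.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    reasons: dict = {}
    accuracy = _ratio(tp + tn, c.total, "Accuracy", reasons)
    tpr = _ratio(tp, tp + fn, "TPR", reasons)
    tnr = _ratio(tn, fp + tn, "TNR", reasons)
    ppv = _ratio(tp, tp + fp, "PPV", reasons)
    npv = _ratio(tn, tn + fn, "NPV", reasons)
    fdr = _ratio(fp, fp + tp, "FDR", reasons)
    fnr = _ratio(fn, tp + fn, "FNR", reasons)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "F1", reasons)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if mcc_den == 0:
        reasons["MCC"] = "undefined: a confusion-matrix margin is empty"
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricsReport(
        accuracy=accuracy, tpr=tpr, tnr=tnr, ppv=ppv, npv=npv,
        fdr=fdr, fnr=fnr, f1=f1, mcc=mcc, reasons=reasons,
    )


def auroc(scores: Sequence[float], truth: Sequence) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    Equals P(score of a random HS > score of a random NS) + 0.5 P(tie).
    """
    t = _as_labels(truth)
    if len(set(t)) < 2:
        raise ValueError("AUROC requires both HS and NS in the truth labels")
    y = (t == POSITIVE).astype(int)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def full_report(
    pred: Sequence, truth: Sequence, scores: Sequence[float] | None = None
) -> MetricsReport:
    """Confusion metrics plus AUROC when scores are supplied."""
    report = classification_metrics(confusion(pred, truth))
    if scores is not None:
        try:
            report.auroc = auroc(scores, truth)
        except ValueError as exc:
            report.reasons["AUROC"] = str(exc)
    return report


def report_frame(reports: Mapping[str, MetricsReport]):
    """Stack named reports into a pandas DataFrame (one row per name)."""
    import pandas as pd

    return pd.DataFrame({k: r.as_dict() for k, r in reports.items()}).T
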
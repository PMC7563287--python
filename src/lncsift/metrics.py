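"""Binary-classification evaluation: confusion-table statistics and ROC/AUC.

SEN = TP/(TP+FN), SPE = TN/(TN+FP), ACC = (TP+TN)/total,
F = 2TP/(2TP+FP+FN), and the Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
A zero denominator yields 0 with a warning (MCC convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .seqio import DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise DataError("confusion counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise DataError("confusion table is empty")


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("zero denominator for %s; reported as 0", name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """SEN, SPE, ACC, MCC and F from a confusion table."""
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return {
        "SEN": _ratio(tp, tp + fn, "SEN"),
        "SPE": _ratio(tn, tn + fp, "SPE"),
        "ACC": (tp + tn) / (tp + tn + fp + fn),
        "MCC": _ratio(tp * tn - fp * fn, mcc_den, "MCC"),
        "F": _ratio(2 * tp, 2 * tp + fp + fn, "F"),
    }


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points (threshold sweep over unique scores) and trapezoid AUC.

    Tied scores are grouped at one threshold, which makes the trapezoid
    area equal to the Mann–Whitney statistic with the 1/2 tie convention.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DataError("ROC needs both classes present in the labels")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, float(_sk_auc(fpr, tpr))
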
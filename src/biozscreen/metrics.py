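"""Classification performance indicators and paired significance testing.

Positive class = diabetic (label 1).  Ratios with a zero denominator are
reported as ``None`` (absent), never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerformanceReport:
    counts: ConfusionCounts
    accuracy: float
    precision: Optional[float]
    recall: Optional[float]
    kappa: Optional[float]

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "kappa": self.kappa,
        }


def _check_pair(labels, predictions) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    if y.size == 0:
        raise ValueError("need at least one sample")
    return y, p


def confusion_counts(labels, predictions) -> ConfusionCounts:
    y, p = _check_pair(labels, predictions)
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def performance(labels, predictions) -> PerformanceReport:
    """Accuracy, precision and recall from the confusion counts.

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    """
    c = confusion_counts(labels, predictions)
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    return PerformanceReport(
        counts=c,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        kappa=cohen_kappa(labels, predictions),
    )


def cohen_kappa(labels, predictions) -> Optional[float]:
    """Chance-corrected agreement kappa = (p0 - pe) / (1 - pe).

    p0 is the observed agreement proportion; pe sums, over classes, the
    product of marginal frequencies P(label = c) * P(prediction = c).
    Perfect agreement with pe = 1 gives kappa = 1; pe = 1 with imperfect
    agreement is undefined and reported as None.
    """
    y, p = _check_pair(labels, predictions)
    n = y.size
    p0 = float(np.mean(y == p))
    classes = np.union1d(y, p)
    pe = float(sum(np.mean(y == c) * np.mean(p == c) for c in classes))
    if pe >= 1.0:
        return 1.0 if p0 == 1.0 else None
    return (p0 - pe) / (1.0 - pe)


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded; the null distribution is enumerated
    exactly for n <= 25 and approximated normally (with tie correction)
    above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero: no information")
    if d.size < 5:
        raise ValueError("need at least 5 nonzero differences")
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=False)
    return float(res.pvalue)
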
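"""Classifier performance metrics: AUC, average PPV and average NPV.

AUC is the Mann-Whitney probability with midrank tie handling.  Average PPV
is the area under the precision-recall curve in its average-precision form
(precision summed over positive recall increments at each distinct score
cutoff); average NPV is the same computation applied to the complemented
problem (scores 1 - s, labels 1 - y), i.e. the area under the
NPV-specificity curve.  Both therefore summarize predictive value across
all score cutoffs.

Implemented as direct rank/cumulative-sum arithmetic: the bootstrap loops
of the bias-corrected evaluation call these metrics tens of thousands of
times, so per-call overhead matters.  The test suite pins each metric to an
exhaustive threshold-sweep oracle (and to pair counting for the AUC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricTriple", "evaluate_metrics"]


@dataclass(frozen=True)
class MetricTriple:
    auc: float
    avg_ppv: float
    avg_npv: float

    def as_array(self) -> np.ndarray:
        return np.array([self.auc, self.avg_ppv, self.avg_npv])


def _auc(scores: np.ndarray, y: np.ndarray) -> float:
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _average_precision(scores: np.ndarray, y: np.ndarray) -> float:
    # sweep distinct cutoffs from the highest score down; at each cutoff the
    # precision is weighted by the recall increment it contributes
    order = np.argsort(scores, kind="mergesort")[::-1]
    s = scores[order]
    t = y[order]
    cum_tp = np.cumsum(t)
    cum_pred = np.arange(1, len(t) + 1)
    # last index of each distinct-score block = the cutoff "score >= s[i]"
    block_end = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    tp = cum_tp[block_end]
    precision = tp / cum_pred[block_end]
    recall = tp / cum_tp[-1]
    return float(np.sum(precision * np.diff(np.r_[0.0, recall])))


def evaluate_metrics(scores: np.ndarray, y: np.ndarray) -> MetricTriple:
    """AUC / average-PPV / average-NPV of a score vector.

    Requires both classes to be present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    if n1 == 0 or n1 == len(y):
        raise ValueError("both classes must be present")
    return MetricTriple(
        _auc(scores, y),
        _average_precision(scores, y),
        _average_precision(1.0 - scores, 1 - y),
    )
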
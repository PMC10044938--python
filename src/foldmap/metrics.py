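"""Per-base evaluation of predicted structures and cross-validation splits.

Samples are *bases*, not cells of the contact map: a base is positive if it
is paired in the reference. A predicted pairing counts as a true positive
only when the partner is exactly right; a base paired to the wrong partner
is a false negative (the reference pair was missed), not a false positive.
This matches the sample definitions used by contact-map benchmarks but
differs from tools that score pairs with partner slack — worth checking when
comparing numbers across papers.

Metrics: ACC = (TP+TN)/total, SEN = TP/(TP+FN), PPV = TP/(TP+FP),
F-score = harmonic mean of SEN and PPV. Aggregation across sequences is
micro by default (sum the counts, then take ratios); a macro option averages
per-sequence metric values instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    sen: float
    ppv: float
    fscore: float
    counts: ConfusionCounts
    #: True when SEN or PPV had a zero denominator and was reported as 0.
    degenerate: bool = False


def _partners(P: np.ndarray) -> np.ndarray:
    """partner[i] = j if base i pairs with j, else -1. Requires row sums <= 1."""
    L = P.shape[0]
    partners = np.full(L, -1, dtype=np.int64)
    ii, jj = np.nonzero(P)
    partners[ii] = jj
    return partners


def confusion_per_base(reference: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN over the bases of one sequence.

    Both arguments are binary symmetric contact maps of the same size with
    at most one partner per base. Per base i: TP if paired identically in
    both; TN if unpaired in both; FP if unpaired in the reference but paired
    in the prediction; FN if paired in the reference and missed or
    mis-partnered in the prediction.
    """
    if reference.shape != predicted.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs predicted {predicted.shape}"
        )
    ref = _partners(reference)
    pred = _partners(predicted)
    ref_paired = ref >= 0
    pred_paired = pred >= 0
    tp = int(np.sum(ref_paired & (ref == pred)))
    tn = int(np.sum(~ref_paired & ~pred_paired))
    fp = int(np.sum(~ref_paired & pred_paired))
    fn = int(np.sum(ref_paired & (ref != pred)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """ACC/SEN/PPV/F-score from confusion counts.

    SEN (resp. PPV) with a zero denominator is reported as 0 and the report
    is flagged degenerate; the F-score is then 0 as well.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    acc = (counts.tp + counts.tn) / counts.total
    degenerate = False
    if counts.tp + counts.fn == 0:
        sen, degenerate = 0.0, True
    else:
        sen = counts.tp / (counts.tp + counts.fn)
    if counts.tp + counts.fp == 0:
        ppv, degenerate = 0.0, True
    else:
        ppv = counts.tp / (counts.tp + counts.fp)
    if sen > 0 and ppv > 0:
        fscore = 2.0 / (1.0 / sen + 1.0 / ppv)
    else:
        fscore, degenerate = 0.0, True
    return MetricsReport(acc=acc, sen=sen, ppv=ppv, fscore=fscore,
                         counts=counts, degenerate=degenerate)


def aggregate_metrics(
    per_sequence: Sequence[ConfusionCounts], macro: bool = False
) -> MetricsReport:
    """Dataset-level metrics: micro (summed counts) or macro (mean of ratios)."""
    if not per_sequence:
        raise ValueError("no sequences to aggregate")
    if not macro:
        total = ConfusionCounts()
        for c in per_sequence:
            total = total + c
        return compute_metrics(total)
    reports = [compute_metrics(c) for c in per_sequence]
    total = ConfusionCounts()
    for c in per_sequence:
        total = total + c
    return MetricsReport(
        acc=float(np.mean([r.acc for r in reports])),
        sen=float(np.mean([r.sen for r in reports])),
        ppv=float(np.mean([r.ppv for r in reports])),
        fscore=float(np.mean([r.fscore for r in reports])),
        counts=total,
        degenerate=any(r.degenerate for r in reports),
    )


def crossval_split(dataset: Sequence, k: int, seed: int) -> List[List]:
    """Random k-fold partition; fold sizes differ by at most one.

    A deterministic function of (dataset order, k, seed).
    """
    n = len(dataset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds: List[List] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(dataset[idx])
    return folds
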
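"""Fitness and comparison statistics.

Balanced accuracy, (sensitivity + specificity)/2, is the fitness of every
evolved classifier: it is insensitive to the class imbalance typical of
short/long-term survival labels.  Model comparisons on the five paired
cross-validation accuracies use an exact Wilcoxon signed-rank test; at
n = 5 the attainable two-sided p-values are multiples of 1/16 with floor
0.0625, so a normal approximation would be meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "balanced_accuracy",
    "balanced_accuracy_from_labels",
    "wilcoxon_signed_rank_exact",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_labels(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        yt = np.asarray(y_true).astype(bool)
        yp = np.asarray(y_pred).astype(bool)
        if yt.shape != yp.shape:
            raise ValueError("label and prediction vectors differ in length")
        return cls(
            tp=int(np.count_nonzero(yt & yp)),
            fp=int(np.count_nonzero(~yt & yp)),
            tn=int(np.count_nonzero(~yt & ~yp)),
            fn=int(np.count_nonzero(yt & ~yp)),
        )


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """(sensitivity + specificity) / 2; requires both classes present."""
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos < 1 or neg < 1:
        raise ValueError("balanced accuracy needs at least one sample of each class")
    return 0.5 * (counts.tp / pos + counts.tn / neg)


def balanced_accuracy_from_labels(y_true, y_pred) -> float:
    return balanced_accuracy(ConfusionCounts.from_labels(y_true, y_pred))


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per value of 2W (W = sum of positive ranks).

    Equivalent to full enumeration of the 2^m sign patterns but computed by
    convolution over the rank multiset; ranks are doubled so that tied
    (average, half-integer) ranks stay integral.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(a, b, sides: str = "two") -> float:
    """Exact signed-rank p-value for paired samples ``a`` and ``b``.

    Zero differences are dropped before ranking; tied absolute differences
    receive average ranks.  ``sides='one'`` returns the tail probability in
    the direction of the observed effect; ``sides='two'`` doubles it,
    capped at 1.  All differences zero gives p = 1.
    """
    if sides not in {"one", "two"}:
        raise ValueError("sides must be 'one' or 'two'")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-d sequences")
    if a.size < 1:
        raise ValueError("need at least one pair")
    d = a - b
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    double_ranks = np.round(2.0 * ranks).astype(np.int64)
    w2 = int(np.round(double_ranks[d > 0].sum()))
    counts = _signed_rank_distribution(double_ranks)
    n_total = 2.0**m
    p_upper = counts[w2:].sum() / n_total
    p_lower = counts[: w2 + 1].sum() / n_total
    p_one = p_upper if p_upper <= p_lower else p_lower
    if sides == "one":
        return float(p_one)
    return float(min(1.0, 2.0 * p_one))
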
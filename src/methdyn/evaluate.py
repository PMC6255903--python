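"""Scoring of pipeline output against planted ground truth.

Recall/precision of segment recovery at reciprocal-overlap matching,
sensitivity of DMR recovery, and F1 of regulatory-edge recovery.  Used by
the synthetic end-to-end demo and by the test suite; real-data analyses do
not need this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import GenomicInterval

__all__ = [
    "reciprocal_overlap",
    "match_intervals",
    "RecoveryScore",
    "score_recovery",
    "edge_f1",
]


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)) — 1.0 only for identical spans."""
    ov = a.overlap_bp(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def match_intervals(
    predicted: Sequence[GenomicInterval],
    truth: Sequence[GenomicInterval],
    min_reciprocal: float = 0.5,
) -> tuple[set[int], set[int]]:
    """Indices of predicted and truth intervals with a reciprocal match."""
    pred_hit: set[int] = set()
    truth_hit: set[int] = set()
    for i, p in enumerate(predicted):
        for j, t in enumerate(truth):
            if reciprocal_overlap(p, t) >= min_reciprocal:
                pred_hit.add(i)
                truth_hit.add(j)
    return pred_hit, truth_hit


@dataclass
class RecoveryScore:
    n_predicted: int
    n_truth: int
    recall: float
    precision: float


def score_recovery(
    predicted: Sequence[GenomicInterval],
    truth: Sequence[GenomicInterval],
    min_reciprocal: float = 0.5,
    ignore: Sequence[GenomicInterval] = (),
) -> RecoveryScore:
    """Recall and precision of interval recovery at reciprocal overlap.

    Predictions overlapping an ``ignore`` interval (e.g. a planted region of
    a different class that legitimately mimics this one at some time point)
    count neither as true nor as false positives.
    """
    keep = [
        p for p in predicted if not any(p.overlaps(iv) for iv in ignore)
    ]
    pred_hit, truth_hit = match_intervals(keep, truth, min_reciprocal)
    recall = len(truth_hit) / len(truth) if truth else 1.0
    precision = len(pred_hit) / len(keep) if keep else 1.0
    return RecoveryScore(len(keep), len(truth), recall, precision)


def edge_f1(
    predicted: Sequence[tuple[str, str, str]],
    truth: Sequence[tuple[str, str, str]],
) -> tuple[float, float, float]:
    """Precision, recall and F1 of (tf, gene, transition) edge recovery."""
    p, t = set(predicted), set(truth)
    if not p and not t:
        return 1.0, 1.0, 1.0
    tp = len(p & t)
    precision = tp / len(p) if p else 0.0
    recall = tp / len(t) if t else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1
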
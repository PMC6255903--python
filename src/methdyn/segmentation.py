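"""Methylome segmentation into unmethylated and low-methylated regions.

In WGBS data, promoters show up as unmethylated regions (UMRs, mean CpG
methylation < 10%) and distal regulatory elements such as enhancers as
low-methylated regions (LMRs, mean methylation in [10%, 50%)), both standing
out against a highly methylated genomic background.

The segmentation here is a deliberately transparent smoothing / merge /
threshold scheme: each CpG's methylation level is smoothed with a 3-CpG
running mean, CpGs with smoothed level < 0.5 are flagged hypomethylated,
consecutive flagged CpGs closer than ``max_gap`` are merged into candidate
regions, and candidates must contain more than 5 CpGs.  Candidates are
classified by their raw mean methylation (UMR < 0.10, LMR < 0.50) and the
whole candidate set is gated by a permutation-based FDR estimate at 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomicInterval, filter_coverage, methylation_levels

__all__ = [
    "SegmentationParams",
    "SegmentCall",
    "SpecificityCall",
    "segment_methylome",
    "estimate_segmentation_fdr",
    "timepoint_specific",
    "segments_to_bed",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds of the segmentation.

    umr_max / lmr_max are the mean-methylation class bounds (UMR: < umr_max;
    LMR: [umr_max, lmr_max)).  min_cpg is the minimum CpG count of a region,
    exclusive (the default 5 means "more than 5 CpGs").  max_gap is the
    largest tolerated distance in bp between consecutive hypomethylated CpGs
    within one candidate.  fdr_target gates the candidate set as a whole via
    ``estimate_segmentation_fdr``.
    """

    umr_max: float = 0.10
    lmr_max: float = 0.50
    hypo_threshold: float = 0.5
    hypo_raw_max: float = 0.6
    smooth_k: int = 3
    max_gap: int = 300
    min_cpg: int = 5  # exclusive: regions need n_cpg > min_cpg
    min_coverage: int = 5
    fdr_target: float = 0.05
    n_permutations: int = 10
    seed: int = 0


@dataclass(frozen=True)
class SegmentCall:
    interval: GenomicInterval
    seg_type: str  # "UMR" | "LMR"
    mean_meth: float
    n_cpg: int
    timepoint: str | None = None


@dataclass(frozen=True)
class SpecificityCall:
    """A segment observed (as its type) at exactly one time point."""

    interval: GenomicInterval
    seg_type: str
    specific_to: str
    status_at_other_timepoints: Mapping[str, str]  # tp -> UMR | LMR | neither


def _running_mean(levels: np.ndarray, k: int) -> np.ndarray:
    """Centered running mean over a window of k CpGs, shrinking at the edges."""
    if k <= 1 or len(levels) <= 1:
        return levels.astype(float)
    half = k // 2
    csum = np.concatenate([[0.0], np.cumsum(levels, dtype=float)])
    n = len(levels)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _candidate_runs(
    positions: np.ndarray, levels: np.ndarray, params: SegmentationParams
) -> list[tuple[int, int]]:
    """Index ranges [i, j) of candidate hypomethylated regions on one chrom."""
    if len(positions) == 0:
        return []
    smoothed = _running_mean(levels, params.smooth_k)
    # a candidate CpG must be hypomethylated both after smoothing and in its
    # own right; the raw bound keeps isolated high-methylation sites flanked
    # by low neighbours from bridging unrelated candidates
    hypo = (smoothed < params.hypo_threshold) & (levels < params.hypo_raw_max)
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(positions)
    while i < n:
        if not hypo[i]:
            i += 1
            continue
        j = i + 1
        while j < n and hypo[j] and positions[j] - positions[j - 1] <= params.max_gap:
            j += 1
        if j - i > params.min_cpg:
            runs.append((i, j))
        i = j
    return runs


def _prepare(calls: pd.DataFrame, params: SegmentationParams) -> pd.DataFrame:
    cg = calls[calls["context"] == "CG"]
    cg = filter_coverage(cg, params.min_coverage)
    return cg


def segment_methylome(
    calls: pd.DataFrame,
    params: SegmentationParams = SegmentationParams(),
    timepoint: str | None = None,
    apply_fdr_gate: bool = True,
) -> list[SegmentCall]:
    """Segment one methylome into UMRs and LMRs.

    ``calls`` is a cytosine report table; only CG-context calls with at least
    ``params.min_coverage`` reads are used (pool symmetric CpGs beforehand
    for dyad-level resolution).  Returns an empty list, with a warning, when
    the candidate set does not pass the permutation FDR gate or when fewer
    than ``min_cpg + 1`` CpGs are available at all.
    """
    cg = _prepare(calls, params)
    if len(cg) <= params.min_cpg:
        warnings.warn("too few covered CpGs to segment; returning no regions")
        return []

    segments: list[SegmentCall] = []
    n_candidates = 0
    for chrom, grp in cg.groupby("chrom", sort=False):
        positions = grp["pos"].to_numpy()
        levels = methylation_levels(grp)
        for i, j in _candidate_runs(positions, levels, params):
            n_candidates += 1
            mean_meth = float(np.mean(levels[i:j]))
            if mean_meth < params.umr_max:
                seg_type = "UMR"
            elif mean_meth < params.lmr_max:
                seg_type = "LMR"
            else:
                continue
            iv = GenomicInterval(
                str(chrom),
                int(positions[i]) - 1,
                int(positions[j - 1]),
                name=seg_type,
                score=round(1000 * mean_meth),
            )
            segments.append(
                SegmentCall(iv, seg_type, mean_meth, int(j - i), timepoint)
            )

    if apply_fdr_gate and n_candidates > 0:
        fdr = estimate_segmentation_fdr(
            cg,
            n_candidates,
            B=params.n_permutations,
            seed=params.seed,
            params=params,
            _prepared=True,
        )
        if fdr >= params.fdr_target:
            warnings.warn(
                f"candidate regions do not pass the FDR gate "
                f"(estimated FDR {fdr:.3f} >= {params.fdr_target}); returning none"
            )
            return []

    segments = _drop_cross_type_overlaps(segments)
    return segments


def _drop_cross_type_overlaps(segments: list[SegmentCall]) -> list[SegmentCall]:
    """Remove any UMR/LMR pair sharing >= 1 bp (ambiguous classification).

    Candidates from one scan are disjoint by construction, so this is a
    safety net for segment lists assembled from several sources.
    """
    drop: set[int] = set()
    by_chrom: dict[str, list[int]] = {}
    for idx, seg in enumerate(segments):
        by_chrom.setdefault(seg.interval.chrom, []).append(idx)
    for idxs in by_chrom.values():
        idxs = sorted(idxs, key=lambda k: segments[k].interval.start)
        for a_i in range(len(idxs)):
            for b_i in range(a_i + 1, len(idxs)):
                a, b = segments[idxs[a_i]], segments[idxs[b_i]]
                if b.interval.start >= a.interval.end:
                    break
                if a.seg_type != b.seg_type and a.interval.overlaps(b.interval):
                    drop.update((idxs[a_i], idxs[b_i]))
    return [s for i, s in enumerate(segments) if i not in drop]


def estimate_segmentation_fdr(
    calls: pd.DataFrame,
    candidate_count: int,
    B: int = 10,
    seed: int = 0,
    params: SegmentationParams = SegmentationParams(),
    _prepared: bool = False,
) -> float:
    """Permutation FDR for a candidate-region count.

    Methylation levels are shuffled within each chromosome (CpG positions
    fixed, destroying spatial structure but keeping the level distribution
    and CpG spacing), candidates are re-counted under each of ``B`` shuffles,
    and the FDR estimate is ``mean(null counts) / max(candidate_count, 1)``,
    clipped to [0, 1].  Zero observed candidates define FDR = 0.
    """
    if B < 2:
        raise ValueError("need at least B=2 permutations")
    if candidate_count == 0:
        return 0.0
    cg = calls if _prepared else _prepare(calls, params)
    rng = np.random.default_rng(seed)
    per_chrom = [
        (grp["pos"].to_numpy(), methylation_levels(grp))
        for _, grp in cg.groupby("chrom", sort=False)
    ]
    null_counts = np.empty(B)
    for b in range(B):
        count = 0
        for positions, levels in per_chrom:
            shuffled = rng.permutation(levels)
            count += len(_candidate_runs(positions, shuffled, params))
        null_counts[b] = count
    fdr = float(np.mean(null_counts)) / max(candidate_count, 1)
    return float(np.clip(fdr, 0.0, 1.0))


def timepoint_specific(
    segments_by_timepoint: Mapping[str, Sequence[SegmentCall]],
) -> list[SpecificityCall]:
    """Segments identified (as their type) at a single time point.

    A segment is specific iff it shares no base with any segment of the same
    type at every other time point (>= 1 bp overlap rule, type-matched: a
    UMR overlapping only an LMR elsewhere is still UMR-specific).  For each
    specific segment the per-time-point status at the other time points is
    recorded (UMR / LMR / neither) for flow-diagram accounting.
    """
    timepoints = list(segments_by_timepoint)
    if len(timepoints) < 2:
        raise ValueError("need at least two time points for specificity analysis")

    # chrom -> tp -> seg_type -> sorted [(start, end)]
    index: dict[str, dict[str, dict[str, list[tuple[int, int]]]]] = {}
    for tp, segs in segments_by_timepoint.items():
        for seg in segs:
            d = index.setdefault(seg.interval.chrom, {}).setdefault(tp, {})
            d.setdefault(seg.seg_type, []).append(
                (seg.interval.start, seg.interval.end)
            )
    for chrom_d in index.values():
        for tp_d in chrom_d.values():
            for lst in tp_d.values():
                lst.sort()

    def _overlaps_any(chrom: str, tp: str, seg_type: str, start: int, end: int) -> bool:
        lst = index.get(chrom, {}).get(tp, {}).get(seg_type)
        if not lst:
            return False
        import bisect

        k = bisect.bisect_left(lst, (start,)) - 1
        for s, e in lst[max(k, 0) :]:
            if s >= end:
                return False
            if e > start:
                return True
        return False

    out: list[SpecificityCall] = []
    for tp, segs in segments_by_timepoint.items():
        others = [t for t in timepoints if t != tp]
        for seg in segs:
            iv = seg.interval
            if any(
                _overlaps_any(iv.chrom, t, seg.seg_type, iv.start, iv.end)
                for t in others
            ):
                continue
            status = {}
            for t in others:
                if _overlaps_any(iv.chrom, t, "UMR", iv.start, iv.end):
                    status[t] = "UMR"
                elif _overlaps_any(iv.chrom, t, "LMR", iv.start, iv.end):
                    status[t] = "LMR"
                else:
                    status[t] = "neither"
            out.append(SpecificityCall(iv, seg.seg_type, tp, status))
    return out


def segments_to_bed(segments: Sequence[SegmentCall]) -> list[GenomicInterval]:
    """BED6-style view: name = UMR/LMR, score = round(1000 * mean methylation)."""
    return [
        replace(
            s.interval,
            name=s.seg_type,
            score=float(round(1000 * s.mean_meth)),
            strand=".",
        )
        for s in segments
    ]
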
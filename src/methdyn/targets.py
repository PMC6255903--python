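"""Assignment of distal regulatory regions to putative target genes.

Regions (LMRs, distal UMRs, DMRs) are cross-referenced against chromatin
interaction maps: curated ("known") and computationally predicted
("predicted") region-gene links consumed as generic interaction tables.  A
region acquires a gene whenever it shares at least one base with the
interaction's region interval; when both evidence classes support the same
(region, gene) pair, the stronger "known" label wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io import GenomicInterval

__all__ = [
    "Interaction",
    "TargetAssignment",
    "read_interactions",
    "write_interactions",
    "assign_targets",
    "summarize_targets",
]

_EVIDENCE_RANK = {"known": 0, "predicted": 1}


@dataclass(frozen=True)
class Interaction:
    """One region-gene link from an interaction map."""

    region: GenomicInterval
    gene: str
    evidence: str  # "known" | "predicted"
    source: str = ""

    def __post_init__(self) -> None:
        if self.evidence not in _EVIDENCE_RANK:
            raise ValueError(f"evidence must be known/predicted, got {self.evidence!r}")


@dataclass(frozen=True)
class TargetAssignment:
    region: GenomicInterval
    gene: str
    evidence: str
    deafness_flag: bool
    region_class: str | None = None  # e.g. UMR / LMR / hyper / hypo
    timepoint: str | None = None


def read_interactions(path: str | Path) -> list[Interaction]:
    """Read a TSV interaction map: chrom, start, end, gene, evidence, source."""
    df = pd.read_csv(
        str(path),
        sep="\t",
        names=["chrom", "start", "end", "gene", "evidence", "source"],
        header=None,
        dtype={"chrom": str, "gene": str, "evidence": str, "source": str},
    )
    df["source"] = df["source"].fillna("")
    return [
        Interaction(
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            r.gene,
            r.evidence,
            r.source,
        )
        for r in df.itertuples(index=False)
    ]


def write_interactions(interactions: Iterable[Interaction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for it in interactions:
            fh.write(
                f"{it.region.chrom}\t{it.region.start}\t{it.region.end}\t"
                f"{it.gene}\t{it.evidence}\t{it.source}\n"
            )


def assign_targets(
    regions: Sequence[GenomicInterval],
    interactions: Sequence[Interaction],
    deafness_genes: Iterable[str] = (),
    region_classes: Sequence[str] | None = None,
    timepoints: Sequence[str] | None = None,
) -> list[TargetAssignment]:
    """Assign genes to regions via >= 1 bp overlap with interaction regions.

    Every overlapping (region, interaction) pair yields an assignment;
    duplicates on (region, gene) collapse to the strongest evidence (known
    beats predicted).  Adding interactions never removes assignments.
    ``region_classes`` / ``timepoints`` are optional per-region labels
    propagated into the assignments for downstream summaries.
    """
    deafness = set(deafness_genes)
    trees: dict[str, IntervalTree] = {}
    for it in interactions:
        trees.setdefault(it.region.chrom, IntervalTree()).addi(
            it.region.start, it.region.end, it
        )

    best: dict[tuple[int, str], TargetAssignment] = {}
    for idx, region in enumerate(regions):
        tree = trees.get(region.chrom)
        if tree is None:
            continue
        for seg in tree.overlap(region.start, region.end):
            it: Interaction = seg.data
            key = (idx, it.gene)
            assignment = TargetAssignment(
                region=region,
                gene=it.gene,
                evidence=it.evidence,
                deafness_flag=it.gene in deafness,
                region_class=region_classes[idx] if region_classes else None,
                timepoint=timepoints[idx] if timepoints else None,
            )
            prev = best.get(key)
            if prev is None or _EVIDENCE_RANK[it.evidence] < _EVIDENCE_RANK[prev.evidence]:
                best[key] = assignment
    return [best[k] for k in sorted(best, key=lambda k: (k[0], k[1]))]


def summarize_targets(assignments: Sequence[TargetAssignment]) -> pd.DataFrame:
    """Unique target-gene counts per (region class, time point).

    Duplicated (region, gene) pairs count once per gene; the deafness-gene
    subset is reported alongside.
    """
    groups: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    for a in assignments:
        key = (a.region_class or "all", a.timepoint or "all")
        genes, deaf = groups.setdefault(key, (set(), set()))
        genes.add(a.gene)
        if a.deafness_flag:
            deaf.add(a.gene)
    rows = [
        {
            "region_class": cls,
            "timepoint": tp,
            "n_genes": len(genes),
            "n_deafness_genes": len(deaf),
        }
        for (cls, tp), (genes, deaf) in sorted(groups.items())
    ]
    return pd.DataFrame(
        rows, columns=["region_class", "timepoint", "n_genes", "n_deafness_genes"]
    )
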
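"""Region annotation: track overlap, regulatory classes, liftover, variants.

Covers the comparative annotation of segmentation output against external
interval tracks (DNase I hypersensitive sites, H3K4me1, CTCF binding sites,
CpG islands, TSSs, validated enhancer fragments), genomic location
classification relative to gene models, coordinate conversion between
assemblies through UCSC chain files, and intersection of regions with GWAS
index SNPs and their linkage-disequilibrium proxies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GenomicInterval, MalformedInputError

__all__ = [
    "OverlapSummary",
    "GeneModel",
    "Chain",
    "ChainMap",
    "VariantRecord",
    "overlap",
    "annotate_regulatory",
    "classify_location",
    "liftover",
    "gwas_ld_overlap",
]


# ---------------------------------------------------------------------------
# Interval overlap


@dataclass
class OverlapSummary:
    """Element-level overlap of a query set against a track.

    percent is 100 * n_overlapping / n_query, or None for an empty query
    (undefined, reported as missing).  partition, when present, splits the
    track-positive queries into named sub-classes with counts and percents
    computed over the positive set only.
    """

    n_query: int
    n_overlapping: int
    percent: float | None
    partition: dict[str, dict[str, float]] | None = None


def _build_trees(track: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in track:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def overlap(
    query: Sequence[GenomicInterval],
    track: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> tuple[OverlapSummary, list[bool]]:
    """Flag each query interval that shares >= min_bp with any track interval.

    The overlap requirement applies per track element (not summed across
    elements).  Returns the summary and the per-query flags.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _build_trees(track)
    flags: list[bool] = []
    for q in query:
        tree = trees.get(q.chrom)
        hit = False
        if tree is not None:
            for seg in tree.overlap(q.start, q.end):
                if min(q.end, seg.end) - max(q.start, seg.begin) >= min_bp:
                    hit = True
                    break
        flags.append(hit)
    n = len(query)
    n_hit = int(sum(flags))
    return OverlapSummary(n, n_hit, 100.0 * n_hit / n if n else None), flags


def annotate_regulatory(
    lmrs: Sequence[GenomicInterval],
    dhs: Sequence[GenomicInterval],
    ctcf_sites: Sequence[GenomicInterval],
    h3k4me1: Sequence[GenomicInterval],
    ctcf_motif_hits: Sequence[bool],
    min_bp: int = 1,
) -> tuple[list[str], OverlapSummary]:
    """Classify LMRs by open-chromatin evidence.

    DHS-positive LMRs that both contain a CTCF motif hit (precomputed by the
    motif module) and overlap a known CTCF binding site are insulator-like
    ("CTCF-class"); the remaining DHS-positive LMRs are "enhancer-class"
    when marked by H3K4me1 and "DHS-other" otherwise; LMRs without DHS
    support are "non-DHS".  The summary's partition reports CTCF-class vs
    enhancer-class percents over the DHS-positive set.
    """
    if len(ctcf_motif_hits) != len(lmrs):
        raise ValueError("ctcf_motif_hits must align with lmrs")
    summary, dhs_flags = overlap(lmrs, dhs, min_bp)
    _, ctcf_flags = overlap(lmrs, ctcf_sites, min_bp)
    _, k4_flags = overlap(lmrs, h3k4me1, min_bp)
    classes: list[str] = []
    for has_dhs, has_ctcf, has_k4, has_motif in zip(
        dhs_flags, ctcf_flags, k4_flags, ctcf_motif_hits
    ):
        if not has_dhs:
            classes.append("non-DHS")
        elif has_motif and has_ctcf:
            classes.append("CTCF-class")
        elif has_k4:
            classes.append("enhancer-class")
        else:
            classes.append("DHS-other")
    n_dhs = int(sum(dhs_flags))
    partition = None
    if n_dhs:
        counts = {
            name: classes.count(name) for name in ("CTCF-class", "enhancer-class")
        }
        partition = {
            name: {"count": c, "percent": 100.0 * c / n_dhs}
            for name, c in counts.items()
        }
    summary.partition = partition
    return classes, summary


# ---------------------------------------------------------------------------
# Location relative to gene models


@dataclass(frozen=True)
class GeneModel:
    """A minimal gene model: body interval, strand, and exon sub-intervals."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    exons: tuple[tuple[int, int], ...] = ()

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def classify_location(
    regions: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    cgi_track: Sequence[GenomicInterval] = (),
    promoter_halfwidth: int = 2000,
    distal_min: int = 5000,
) -> pd.DataFrame:
    """Locate regions relative to genes: promoter / exonic / intronic / intergenic.

    A region within ``promoter_halfwidth`` bp of a TSS is a promoter;
    otherwise a region inside a gene body is exonic if it touches an exon,
    else intronic; everything else is intergenic.  The signed distance to
    the nearest TSS (0 when the region contains it, negative when the
    region lies left of the TSS on the chromosome) and a "distal" flag
    (|distance| > ``distal_min``) are reported, along with a three-way band
    label promoter / proximal / distal and a CpG-island overlap flag.
    Each region receives exactly one location class.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    for gm in gene_models:
        tss_by_chrom.setdefault(gm.chrom, [])  # type: ignore[arg-type]
    tmp: dict[str, list[int]] = {c: [] for c in tss_by_chrom}
    for gm in gene_models:
        tmp[gm.chrom].append(gm.tss)
    tss_by_chrom = {c: np.array(sorted(v)) for c, v in tmp.items()}

    gene_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    for gm in gene_models:
        gene_trees.setdefault(gm.chrom, IntervalTree()).addi(gm.start, gm.end)
        for s, e in gm.exons:
            exon_trees.setdefault(gm.chrom, IntervalTree()).addi(s, e)
    cgi_trees = _build_trees(cgi_track)

    rows = []
    for r in regions:
        tss = tss_by_chrom.get(r.chrom)
        if tss is None or len(tss) == 0:
            dist: float = np.inf
        else:
            # gap between the region and each TSS point; 0 if contained
            left = tss - (r.end - 1)  # >0 when TSS right of region
            right = r.start - tss  # >0 when TSS left of region
            gaps = np.where(left > 0, left, np.where(right > 0, -right, 0))
            dist = float(gaps[np.argmin(np.abs(gaps))])
        is_promoter = np.isfinite(dist) and abs(dist) <= promoter_halfwidth
        if is_promoter:
            location = "promoter"
        else:
            gtree = gene_trees.get(r.chrom)
            in_gene = bool(gtree is not None and gtree.overlap(r.start, r.end))
            if in_gene:
                etree = exon_trees.get(r.chrom)
                in_exon = bool(etree is not None and etree.overlap(r.start, r.end))
                location = "exonic" if in_exon else "intronic"
            else:
                location = "intergenic"
        distal = (not np.isfinite(dist)) or abs(dist) > distal_min
        band = "promoter" if is_promoter else ("distal" if distal else "proximal")
        ctree = cgi_trees.get(r.chrom)
        cgi = bool(ctree is not None and ctree.overlap(r.start, r.end))
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "location": location,
                "cgi": cgi,
                "tss_distance": dist if np.isfinite(dist) else np.nan,
                "distal": bool(distal),
                "band": band,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "location",
            "cgi",
            "tss_distance",
            "distal",
            "band",
        ],
    )


# ---------------------------------------------------------------------------
# Chain-file liftover


@dataclass
class Chain:
    """One UCSC alignment chain: header fields plus ungapped blocks.

    Blocks are (t_start, t_end, q_start) triples in chain-local coordinates:
    target coordinates are forward-strand, query coordinates are on
    ``q_strand`` (converted to forward-strand at mapping time).  Source and
    target block lengths are equal by construction.
    """

    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: list[tuple[int, int, int]] = field(default_factory=list)


class ChainMap:
    """An ordered collection of chains indexed by source chromosome."""

    def __init__(self, chains: Sequence[Chain]):
        self.chains = list(chains)
        self._by_chrom: dict[str, list[Chain]] = {}
        for ch in self.chains:
            self._by_chrom.setdefault(ch.t_name, []).append(ch)

    @classmethod
    def from_file(cls, path: str | Path) -> "ChainMap":
        chains: list[Chain] = []
        current: Chain | None = None
        t_off = q_off = 0
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if line.startswith("chain"):
                    parts = line.split()
                    if len(parts) != 13 or parts[4] != "+":
                        raise MalformedInputError(
                            f"{path}: malformed chain header at line {lineno}"
                        )
                    current = Chain(
                        score=float(parts[1]),
                        t_name=parts[2],
                        t_size=int(parts[3]),
                        t_start=int(parts[5]),
                        t_end=int(parts[6]),
                        q_name=parts[7],
                        q_size=int(parts[8]),
                        q_strand=parts[9],
                        q_start=int(parts[10]),
                        q_end=int(parts[11]),
                        chain_id=parts[12],
                    )
                    if current.q_strand not in "+-":
                        raise MalformedInputError(
                            f"{path}: bad query strand at line {lineno}"
                        )
                    chains.append(current)
                    t_off, q_off = current.t_start, current.q_start
                else:
                    if current is None:
                        raise MalformedInputError(
                            f"{path}: alignment line before chain header at line {lineno}"
                        )
                    parts = line.split()
                    try:
                        nums = [int(x) for x in parts]
                    except ValueError as exc:
                        raise MalformedInputError(
                            f"{path}: malformed alignment line at line {lineno}"
                        ) from exc
                    if len(nums) == 3:
                        size, dt, dq = nums
                    elif len(nums) == 1:
                        size, dt, dq = nums[0], 0, 0
                        # terminal block closes the chain
                    else:
                        raise MalformedInputError(
                            f"{path}: malformed alignment line at line {lineno}"
                        )
                    current.blocks.append((t_off, t_off + size, q_off))
                    t_off += size + dt
                    q_off += size + dq
                    if len(nums) == 1:
                        current = None
        return cls(chains)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ch in self.chains:
                fh.write(
                    f"chain {ch.score:g} {ch.t_name} {ch.t_size} + "
                    f"{ch.t_start} {ch.t_end} {ch.q_name} {ch.q_size} "
                    f"{ch.q_strand} {ch.q_start} {ch.q_end} {ch.chain_id}\n"
                )
                for k, (ts, te, qs) in enumerate(ch.blocks):
                    size = te - ts
                    if k == len(ch.blocks) - 1:
                        fh.write(f"{size}\n\n")
                    else:
                        nts, _, nqs = ch.blocks[k + 1]
                        fh.write(f"{size} {nts - te} {nqs - (qs + size)}\n")

    def invert(self) -> "ChainMap":
        """Swap source and target (forward-strand chains only)."""
        inv: list[Chain] = []
        for ch in self.chains:
            if ch.q_strand != "+":
                raise NotImplementedError(
                    "inversion of minus-strand chains is not supported"
                )
            inv.append(
                Chain(
                    score=ch.score,
                    t_name=ch.q_name,
                    t_size=ch.q_size,
                    t_start=ch.q_start,
                    t_end=ch.q_end,
                    q_name=ch.t_name,
                    q_size=ch.t_size,
                    q_strand="+",
                    q_start=ch.t_start,
                    q_end=ch.t_end,
                    chain_id=ch.chain_id,
                    blocks=[(qs, qs + (te - ts), ts) for ts, te, qs in ch.blocks],
                )
            )
        return ChainMap(inv)


@dataclass
class LiftoverResult:
    mapped: list[tuple[GenomicInterval, GenomicInterval]]
    unmapped: list[tuple[GenomicInterval, str]]  # reason: partial | split | no_chain

    @property
    def mapped_intervals(self) -> list[GenomicInterval]:
        return [m for _, m in self.mapped]


def _chain_coverage(chain: Chain, start: int, end: int) -> int:
    cov = 0
    for ts, te, _ in chain.blocks:
        cov += max(0, min(end, te) - max(start, ts))
    return cov


def _map_through(chain: Chain, start: int, end: int) -> GenomicInterval | None:
    """Image of the covered bases of [start, end) through one chain."""
    q_positions: list[int] = []
    for ts, te, qs in chain.blocks:
        s, e = max(start, ts), min(end, te)
        if s >= e:
            continue
        q_lo = qs + (s - ts)
        q_hi = qs + (e - ts)  # exclusive
        if chain.q_strand == "+":
            q_positions.extend((q_lo, q_hi - 1))
        else:
            q_positions.extend(
                (chain.q_size - 1 - (q_hi - 1), chain.q_size - 1 - q_lo)
            )
    if not q_positions:
        return None
    lo, hi = min(q_positions), max(q_positions)
    strand = "+" if chain.q_strand == "+" else "-"
    return GenomicInterval(chain.q_name, lo, hi + 1, strand=strand)


def liftover(
    intervals: Sequence[GenomicInterval],
    chain_map: ChainMap,
    min_match: float = 0.95,
) -> LiftoverResult:
    """Map intervals to the chain map's query assembly.

    An interval maps iff at least ``min_match`` of its bases fall in aligned
    blocks of a single chain; its image is the span of the mapped bases.
    Failures are reported with a reason: "no_chain" (no chain touches the
    interval), "split" (only a combination of chains reaches ``min_match``),
    or "partial" (insufficient aligned coverage).
    """
    if not 0 < min_match <= 1:
        raise ValueError("min_match must be in (0, 1]")
    mapped: list[tuple[GenomicInterval, GenomicInterval]] = []
    unmapped: list[tuple[GenomicInterval, str]] = []
    for iv in intervals:
        chains = chain_map._by_chrom.get(iv.chrom, [])
        covs = [(_chain_coverage(ch, iv.start, iv.end), ch) for ch in chains]
        covs = [(c, ch) for c, ch in covs if c > 0]
        if not covs:
            unmapped.append((iv, "no_chain"))
            continue
        covs.sort(key=lambda x: (x[0], x[1].score), reverse=True)
        best_cov, best_chain = covs[0]
        need = min_match * len(iv)
        if best_cov >= need:
            image = _map_through(best_chain, iv.start, iv.end)
            assert image is not None
            mapped.append((iv, image))
        elif sum(c for c, _ in covs) >= need:
            unmapped.append((iv, "split"))
        else:
            unmapped.append((iv, "partial"))
    return LiftoverResult(mapped, unmapped)


# ---------------------------------------------------------------------------
# GWAS / LD intersection


@dataclass(frozen=True)
class VariantRecord:
    """A GWAS index SNP or one of its LD proxies (r2 to the index SNP)."""

    rsid: str
    chrom: str
    pos: int
    trait: str
    is_proxy: bool
    r2: float
    index_rsid: str

    def __post_init__(self) -> None:
        if not 0 <= self.r2 <= 1:
            raise ValueError("r2 must be in [0, 1]")


def gwas_ld_overlap(
    index_snps: pd.DataFrame,
    ld_table: pd.DataFrame | None,
    lifted_lmrs: Sequence[GenomicInterval],
    interactions: Sequence | None = None,
    r2_min: float = 0.5,
    max_distance: int = 500_000,
) -> pd.DataFrame:
    """Variants (index SNPs plus qualifying LD proxies) falling inside LMRs.

    ``index_snps`` columns: rsid, chrom, pos (0-based), trait.  ``ld_table``
    columns: index_rsid, proxy_rsid, chrom, pos, r2, distance.  Proxies
    require r2 >= ``r2_min`` and |distance| <= ``max_distance``.  When an
    interaction map is given (records with a ``region`` interval and a
    ``gene``), target genes of the harbouring LMR are attached.
    """
    variants: list[VariantRecord] = []
    for row in index_snps.itertuples(index=False):
        variants.append(
            VariantRecord(row.rsid, str(row.chrom), int(row.pos), str(row.trait), False, 1.0, row.rsid)
        )
    trait_of = {row.rsid: str(row.trait) for row in index_snps.itertuples(index=False)}
    if ld_table is not None:
        for row in ld_table.itertuples(index=False):
            if float(row.r2) < r2_min or abs(int(row.distance)) > max_distance:
                continue
            variants.append(
                VariantRecord(
                    row.proxy_rsid,
                    str(row.chrom),
                    int(row.pos),
                    trait_of.get(row.index_rsid, ""),
                    True,
                    float(row.r2),
                    row.index_rsid,
                )
            )

    lmr_trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(lifted_lmrs):
        lmr_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    inter_trees: dict[str, IntervalTree] = {}
    if interactions is not None:
        for rec in interactions:
            region = rec.region
            inter_trees.setdefault(region.chrom, IntervalTree()).addi(
                region.start, region.end, rec.gene
            )

    rows = []
    for v in variants:
        tree = lmr_trees.get(v.chrom)
        if tree is None:
            continue
        hits = tree.overlap(v.pos, v.pos + 1)
        for hit in hits:
            lmr = lifted_lmrs[hit.data]
            genes: list[str] = []
            itree = inter_trees.get(lmr.chrom)
            if itree is not None:
                genes = sorted(
                    {seg.data for seg in itree.overlap(lmr.start, lmr.end)}
                )
            rows.append(
                {
                    "rsid": v.rsid,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "trait": v.trait,
                    "is_proxy": v.is_proxy,
                    "r2": v.r2,
                    "index_rsid": v.index_rsid,
                    "lmr_start": lmr.start,
                    "lmr_end": lmr.end,
                    "genes": ",".join(genes),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "rsid",
            "chrom",
            "pos",
            "trait",
            "is_proxy",
            "r2",
            "index_rsid",
            "lmr_start",
            "lmr_end",
            "genes",
        ],
    )
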
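"""Synthetic methylome datasets with known planted structure.

The generator emulates a three-time-point WGBS study of a developing
tissue: an embryonic stage, a perinatal stage and a mature stage, with a
"developmental" transition (DevTrans) between the first two and a
"maturation" transition (MatTrans) between the last two.  Emitted data
reproduce the qualitative features the downstream stages rely on:

* CG-context bimodality — a highly methylated background (default 85%)
  with planted unmethylated regions (UMRs, 3%) at gene promoters / CpG
  islands and low-methylated regions (LMRs, 30%) at TSS-distal positions;
* planted differentially methylated regions (DMRs) whose methylation
  changes by more than 30 percentage points across one transition;
* low non-CpG (CHG/CHH) methylation, rising in the mature time point;
* annotation tracks (TSS, CpG islands, DNase hypersensitive sites,
  H3K4me1, CTCF sites, validated-enhancer-like fragments) wired to the
  planted regions at configurable coverage fractions;
* TF motif instances written into planted LMR/DMR sequence, an
  interaction map linking each LMR/DMR to exactly one gene, and an
  expression table anti-correlated with planted DMR direction.

Every stochastic choice flows from a single seed, so a fixed spec yields
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .io import (
    CYTOSINE_REPORT_COLUMNS,
    GenomicInterval,
    write_bed,
    write_cytosine_report,
    write_fasta,
)
from .motifs import PWMotif, write_jaspar
from .targets import Interaction, write_interactions

__all__ = [
    "SyntheticSpec",
    "SyntheticGenome",
    "GroundTruth",
    "PlantedDMR",
    "InvalidSpecError",
    "generate_genome",
    "generate_methylomes",
    "generate_expression",
    "write_dataset",
]

DEV_TRANS = "DevTrans"
MAT_TRANS = "MatTrans"


class InvalidSpecError(ValueError):
    """A synthetic spec violates its own invariants or does not fit."""


# Built-in synthetic TF motifs (consensus 10-mers, counts 97:1:1:1) and a
# CTCF-like 14-mer used for the insulator-class LMRs.
_TF_CONSENSUS = {"Tfa": "ATGACGTCAT", "Tfb": "GCTGAGTCAC"}
_CTCF_NAME = "Ctcf"
_CTCF_CONSENSUS = "CCGCGAGGTGGCAG"


def _consensus_motif(name: str, consensus: str) -> PWMotif:
    counts = np.full((len(consensus), 4), 1.0)
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = 97.0
    return PWMotif.from_counts(name, counts)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic study.

    Methylation levels are fractions; ``dmr_delta`` is the planted
    between-condition difference and must exceed the 0.30 calling gate.
    ``mch_rate_by_timepoint`` gives the flat non-CpG methylation probability
    per time point (the mature stage is elevated by default).
    """

    genome_length: int = 600_000  # bases per chromosome
    n_chroms: int = 1
    gc_fraction: float = 0.42
    n_umr: int = 10
    n_lmr: int = 20
    n_dmr: int = 16
    umr_level: float = 0.03
    lmr_level: float = 0.30
    background_level: float = 0.85
    dmr_delta: float = 0.40
    coverage_mean: float = 15.0
    mch_rate_by_timepoint: tuple[float, ...] = (0.002, 0.002, 0.012)
    n_motif_planted: int = 12
    seed: int = 0
    timepoints: tuple[str, ...] = ("embryonic", "perinatal", "mature")
    # track wiring
    cgi_at_tss_fraction: float = 0.8
    dhs_cover_fraction: float = 0.9
    ctcf_fraction: float = 0.12  # of DHS-positive LMRs
    n_vista: int = 5
    vista_hit_fraction: float = 0.8
    # layout
    umr_length: int = 1500
    lmr_length: int = 800
    dmr_length: int = 800
    tss_margin: int = 6000  # clearance around a TSS-bearing slot
    base_gap: int = 300
    # interactions / expression
    known_fraction: float = 0.5
    compliance: float = 0.9
    n_extra_genes: int = 5
    conversion_rate: float = 0.995
    read_length: int = 100

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise InvalidSpecError("genome_length must be positive")
        if self.n_chroms <= 0:
            raise InvalidSpecError("n_chroms must be positive")
        if not 0 < self.gc_fraction < 1:
            raise InvalidSpecError("gc_fraction must be in (0, 1)")
        if not self.umr_level < 0.10:
            raise InvalidSpecError("umr_level must be below 0.10")
        if not 0.10 <= self.lmr_level < 0.50:
            raise InvalidSpecError("lmr_level must be in [0.10, 0.50)")
        if not self.background_level >= 0.50:
            raise InvalidSpecError("background_level must be at least 0.50")
        if not abs(self.dmr_delta) > 0.30:
            raise InvalidSpecError("|dmr_delta| must exceed the 0.30 calling gate")
        if min(self.n_umr, self.n_lmr, self.n_dmr, self.n_motif_planted) < 0:
            raise InvalidSpecError("region and motif counts must be non-negative")
        if len(self.mch_rate_by_timepoint) != len(self.timepoints):
            raise InvalidSpecError("need one non-CpG rate per time point")
        if self.background_level - abs(self.dmr_delta) < 0:
            raise InvalidSpecError("dmr_delta larger than the background level")

    @property
    def transitions(self) -> list[tuple[str, int, int]]:
        names = [DEV_TRANS, MAT_TRANS]
        return [
            (names[k] if k < 2 else f"transition{k}", k, k + 1)
            for k in range(len(self.timepoints) - 1)
        ]


@dataclass(frozen=True)
class PlantedDMR:
    interval: GenomicInterval
    transition: str
    direction: str  # "hyper" | "hypo" (later minus earlier)
    tf: str
    gene: str
    levels: tuple[float, ...]  # per time point


@dataclass
class GroundTruth:
    """Planted structure, the acceptance surface for every downstream stage."""

    planted_umrs: dict[str, list[GenomicInterval]]  # per time point
    planted_lmrs: dict[str, list[GenomicInterval]]
    planted_dmrs: list[PlantedDMR]
    planted_motif_sites: list[tuple[GenomicInterval, str]]
    planted_edges: list[tuple[str, str, str]]  # (tf, gene, transition)
    expression_truth: dict[str, dict[str, str]]  # gene -> transition -> up/down


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    tracks: dict[str, list[GenomicInterval]]
    gene_models: list[GeneModel]
    interactions: list[Interaction]
    motifs: list[PWMotif]
    umrs: list[GenomicInterval]
    lmrs: list[GenomicInterval]
    dmrs: list[PlantedDMR]
    motif_sites: list[tuple[GenomicInterval, str]]
    edges: list[tuple[str, str, str]]
    lambda_sequence: str

    @property
    def genome_size(self) -> int:
        return sum(len(s) for s in self.sequences.values())


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def _cgi_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    seq = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=[0.16, 0.34, 0.34, 0.16]
    )
    for i in range(0, n - 1, 8):  # guarantee CpG density
        seq[i], seq[i + 1] = ord("C"), ord("G")
    return seq


def generate_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """Lay out and synthesize the genome, tracks and interaction map.

    Planted regions are non-overlapping, separated by background, and
    TSS-bearing slots (promoter UMRs, target genes) keep a clearance of
    ``spec.tss_margin`` so distal regions stay unambiguously distal.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)

    # region slots, round-robin across chromosomes
    slot_types = (
        ["umr"] * spec.n_umr + ["lmr"] * spec.n_lmr + ["dmr"] * spec.n_dmr
    )
    rng.shuffle(slot_types)
    n_target_genes = spec.n_lmr + spec.n_dmr
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    slots_by_chrom: dict[str, list[str]] = {c: [] for c in chrom_names}
    for i, st in enumerate(slot_types):
        slots_by_chrom[chrom_names[i % spec.n_chroms]].append(st)
    genes_by_chrom: dict[str, int] = {c: 0 for c in chrom_names}
    for i in range(n_target_genes + spec.n_extra_genes):
        genes_by_chrom[chrom_names[i % spec.n_chroms]] += 1

    lengths = {"umr": spec.umr_length, "lmr": spec.lmr_length, "dmr": spec.dmr_length}
    gene_body = 2000

    sequences: dict[str, np.ndarray] = {}
    umrs: list[GenomicInterval] = []
    lmrs: list[GenomicInterval] = []
    dmr_slots: list[GenomicInterval] = []
    gene_models: list[GeneModel] = []
    cgi_track: list[GenomicInterval] = []
    tail_gene_names: list[str] = []
    gene_idx = 0

    for chrom in chrom_names:
        seq = _random_sequence(rng, spec.genome_length, spec.gc_fraction)
        cursor = 2000
        prev_needs_margin = False
        for st in slots_by_chrom[chrom]:
            needs_margin = st == "umr"
            gap = spec.base_gap + int(rng.integers(0, 200))
            if prev_needs_margin or needs_margin:
                gap += spec.tss_margin
            start = cursor + gap
            end = start + lengths[st]
            if end > spec.genome_length - spec.tss_margin - 1000:
                raise InvalidSpecError(
                    f"genome_length {spec.genome_length} too small for the "
                    f"requested regions on {chrom}"
                )
            iv = GenomicInterval(chrom, start, end)
            if st == "umr":
                umrs.append(iv)
                tss = (start + end) // 2
                gene = GeneModel(
                    chrom,
                    tss,
                    tss + gene_body,
                    "+",
                    f"gene{gene_idx:04d}",
                    ((tss, tss + 200), (tss + 900, tss + 1100)),
                )
                gene_models.append(gene)
                gene_idx += 1
                if rng.random() < spec.cgi_at_tss_fraction:
                    cgi_start = max(start, tss - 400)
                    cgi_end = min(end, tss + 400)
                    seq[cgi_start:cgi_end] = _cgi_sequence(rng, cgi_end - cgi_start)
                    cgi_track.append(GenomicInterval(chrom, cgi_start, cgi_end))
                cursor = max(end, tss + gene_body)
            else:
                (lmrs if st == "lmr" else dmr_slots).append(iv)
                cursor = end
            prev_needs_margin = needs_margin
        # target + extra genes in a tail block, clear of the regions
        cursor += spec.tss_margin
        for _ in range(genes_by_chrom[chrom]):
            tss = cursor + 500
            name = f"gene{gene_idx:04d}"
            gene_models.append(
                GeneModel(
                    chrom,
                    tss,
                    tss + gene_body,
                    "+",
                    name,
                    ((tss, tss + 200), (tss + 900, tss + 1100)),
                )
            )
            tail_gene_names.append(name)
            gene_idx += 1
            cursor = tss + gene_body + 500
        if cursor > spec.genome_length - 1000:
            raise InvalidSpecError(
                f"genome_length {spec.genome_length} too small for the requested "
                f"regions on {chrom} (needs about {cursor + 1000})"
            )
        sequences[chrom] = seq

    # DMR schedule: alternate transitions, then alternate directions
    motifs = [_consensus_motif(n, c) for n, c in _TF_CONSENSUS.items()]
    ctcf_motif = _consensus_motif(_CTCF_NAME, _CTCF_CONSENSUS)
    tf_names = list(_TF_CONSENSUS)
    transitions = spec.transitions
    target_gene_names = tail_gene_names[:n_target_genes]
    # interaction targets: LMRs first, then DMRs, one gene each
    lo = spec.background_level - abs(spec.dmr_delta)
    hi = spec.background_level
    dmrs: list[PlantedDMR] = []
    for i, iv in enumerate(dmr_slots):
        tname, k_from, _ = transitions[i % len(transitions)]
        direction = "hypo" if (i // len(transitions)) % 2 == 0 else "hyper"
        if direction == "hypo":
            levels = tuple(
                hi if t <= k_from else lo for t in range(len(spec.timepoints))
            )
        else:
            levels = tuple(
                lo if t <= k_from else hi for t in range(len(spec.timepoints))
            )
        # one factor per transition keeps each (transition, direction) DMR
        # set homogeneous, as a coordinated regulatory program would
        tf = tf_names[(i % len(transitions)) % len(tf_names)]
        gene = target_gene_names[spec.n_lmr + i]
        dmrs.append(PlantedDMR(iv, tname, direction, tf, gene, levels))

    interactions: list[Interaction] = []
    for i, iv in enumerate(lmrs):
        evidence = "known" if rng.random() < spec.known_fraction else "predicted"
        interactions.append(Interaction(iv, target_gene_names[i], evidence, "synthetic"))
    for d in dmrs:
        evidence = "known" if rng.random() < spec.known_fraction else "predicted"
        interactions.append(Interaction(d.interval, d.gene, evidence, "synthetic"))

    # plant motif instances: the first TF motif into a subset of LMRs (the
    # enrichment screen's signal), each DMR's TF motif into the DMR
    motif_sites: list[tuple[GenomicInterval, str]] = []

    def plant(seq_map: dict[str, np.ndarray], iv: GenomicInterval, consensus: str) -> None:
        offset = int(rng.integers(0, len(iv) - len(consensus)))
        pos = iv.start + offset
        arr = np.frombuffer(consensus.encode(), dtype=np.uint8)
        seq_map[iv.chrom][pos : pos + len(consensus)] = arr
        motif_sites.append(
            (GenomicInterval(iv.chrom, pos, pos + len(consensus)), _name_of(consensus))
        )

    def _name_of(consensus: str) -> str:
        for n, c in _TF_CONSENSUS.items():
            if c == consensus:
                return n
        return _CTCF_NAME

    n_plant = min(spec.n_motif_planted, len(lmrs))
    planted_lmr_idx = rng.choice(len(lmrs), size=n_plant, replace=False) if n_plant else []
    for i in sorted(planted_lmr_idx):
        plant(sequences, lmrs[i], _TF_CONSENSUS["Tfa"])
    for d in dmrs:
        plant(sequences, d.interval, _TF_CONSENSUS[d.tf])

    # tracks wired to the planted LMRs
    dhs: list[GenomicInterval] = []
    ctcf_sites: list[GenomicInterval] = []
    h3k4me1: list[GenomicInterval] = []
    n_dhs = int(round(spec.dhs_cover_fraction * len(lmrs)))
    dhs_idx = sorted(rng.choice(len(lmrs), size=n_dhs, replace=False)) if n_dhs else []
    n_ctcf = int(round(spec.ctcf_fraction * len(dhs_idx)))
    ctcf_idx = set(
        int(i) for i in (rng.choice(dhs_idx, size=n_ctcf, replace=False) if n_ctcf else [])
    )
    for i in dhs_idx:
        iv = lmrs[i]
        dhs.append(GenomicInterval(iv.chrom, max(0, iv.start - 100), iv.end + 100))
        if i in ctcf_idx:
            ctcf_sites.append(GenomicInterval(iv.chrom, iv.start, iv.end))
            plant(sequences, iv, _CTCF_CONSENSUS)
        else:
            h3k4me1.append(GenomicInterval(iv.chrom, max(0, iv.start - 200), iv.end + 200))

    # enhancer-validation-like fragments: most overlap an LMR, the rest fall
    # in background so recovery stays below 100%
    vista: list[GenomicInterval] = []
    n_vista_hit = int(round(spec.vista_hit_fraction * spec.n_vista))
    if spec.n_vista and lmrs:
        hit_idx = rng.choice(len(lmrs), size=min(n_vista_hit, len(lmrs)), replace=False)
        for i in sorted(hit_idx):
            iv = lmrs[i]
            vista.append(GenomicInterval(iv.chrom, max(0, iv.start - 300), iv.end + 300))
        for _ in range(spec.n_vista - len(vista)):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            start = spec.genome_length - 1500 - int(rng.integers(0, 800))
            vista.append(GenomicInterval(chrom, start, start + 1000))

    tss_track = [
        GenomicInterval(gm.chrom, gm.tss, gm.tss + 1, name=gm.name)
        for gm in gene_models
    ]

    edges = [(d.tf, d.gene, d.transition) for d in dmrs]
    lambda_seq = _random_sequence(rng, 3000, 0.5)

    return SyntheticGenome(
        sequences={c: s.tobytes().decode() for c, s in sequences.items()},
        tracks={
            "tss": tss_track,
            "cgi": cgi_track,
            "dhs": dhs,
            "ctcf": ctcf_sites,
            "h3k4me1": h3k4me1,
            "vista": vista,
        },
        gene_models=gene_models,
        interactions=interactions,
        motifs=motifs + [ctcf_motif],
        umrs=umrs,
        lmrs=lmrs,
        dmrs=dmrs,
        motif_sites=motif_sites,
        edges=edges,
        lambda_sequence=lambda_seq.tobytes().decode(),
    )


# ---------------------------------------------------------------------------
# Methylomes


def _cytosine_sites(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """0-based positions, strands, contexts and trinucleotides of all Cs."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    C, G = ord("C"), ord("G")
    plus = np.nonzero(arr == C)[0]
    minus = np.nonzero(arr == G)[0]

    def base_at(idx: np.ndarray) -> np.ndarray:
        out = np.zeros(len(idx), dtype=np.uint8)
        ok = (idx >= 0) & (idx < len(arr))
        out[ok] = arr[idx[ok]]
        out[~ok] = ord("N")
        return out

    p1, p2 = base_at(plus + 1), base_at(plus + 2)
    ctx_plus = np.where(p1 == G, "CG", np.where(p2 == G, "CHG", "CHH"))
    m1, m2 = base_at(minus - 1), base_at(minus - 2)
    ctx_minus = np.where(m1 == C, "CG", np.where(m2 == C, "CHG", "CHH"))

    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    tri_plus = np.char.add(
        np.char.add(np.full(len(plus), "C"), base_at(plus + 1).view("S1").astype(str)),
        base_at(plus + 2).view("S1").astype(str),
    )
    tri_minus = np.char.add(
        np.char.add(np.full(len(minus), "C"), comp[base_at(minus - 1)].view("S1").astype(str)),
        comp[base_at(minus - 2)].view("S1").astype(str),
    )

    positions = np.concatenate([plus, minus])
    strands = np.concatenate(
        [np.full(len(plus), "+"), np.full(len(minus), "-")]
    )
    contexts = np.concatenate([ctx_plus, ctx_minus])
    trinucs = np.concatenate([tri_plus, tri_minus])
    # chromosome-boundary cytosines have N-padded 3-mers and no defined
    # context; they are not emitted
    keep = np.char.find(trinucs, "N") < 0
    positions, strands = positions[keep], strands[keep]
    contexts, trinucs = contexts[keep], trinucs[keep]
    order = np.argsort(positions, kind="stable")
    return positions[order], strands[order], contexts[order], trinucs[order]


def generate_methylomes(
    spec: SyntheticSpec, genome: SyntheticGenome
) -> tuple[dict[str, pd.DataFrame], GroundTruth, pd.DataFrame]:
    """Emit one cytosine call table per time point, plus the ground truth
    and an unmethylated spike-in control table for conversion-rate QC.

    Per cytosine and time point, coverage is Poisson(coverage_mean) floored
    at 1 and the methylated count is Binomial(coverage, level), where level
    is the planted region level (CG context), the background level, or the
    time point's flat non-CpG rate.  Both strands of a CpG dyad are emitted.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_tp = len(spec.timepoints)

    # planted interval table per chromosome: (start, end, levels per tp)
    region_by_chrom: dict[str, list[tuple[int, int, tuple[float, ...]]]] = {}
    for iv in genome.umrs:
        region_by_chrom.setdefault(iv.chrom, []).append(
            (iv.start, iv.end, (spec.umr_level,) * n_tp)
        )
    for iv in genome.lmrs:
        region_by_chrom.setdefault(iv.chrom, []).append(
            (iv.start, iv.end, (spec.lmr_level,) * n_tp)
        )
    for d in genome.dmrs:
        region_by_chrom.setdefault(d.interval.chrom, []).append(
            (d.interval.start, d.interval.end, d.levels)
        )
    for lst in region_by_chrom.values():
        lst.sort()

    frames: dict[str, list[pd.DataFrame]] = {tp: [] for tp in spec.timepoints}
    for chrom, seq in genome.sequences.items():
        positions, strands, contexts, trinucs = _cytosine_sites(seq)
        regions = region_by_chrom.get(chrom, [])
        starts = np.array([r[0] for r in regions], dtype=int)
        ends = np.array([r[1] for r in regions], dtype=int)
        level_matrix = np.array([r[2] for r in regions], dtype=float).reshape(
            len(regions), n_tp
        )
        idx = np.searchsorted(starts, positions, side="right") - 1 if len(regions) else None
        is_cg = contexts == "CG"
        for t, tp in enumerate(spec.timepoints):
            levels = np.full(len(positions), spec.mch_rate_by_timepoint[t])
            cg_levels = np.full(len(positions), spec.background_level)
            if idx is not None:
                in_region = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
                cg_levels[in_region] = level_matrix[idx[in_region], t]
            levels[is_cg] = cg_levels[is_cg]
            coverage = np.maximum(rng.poisson(spec.coverage_mean, len(positions)), 1)
            n_meth = rng.binomial(coverage, levels)
            frames[tp].append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": positions + 1,
                        "strand": strands,
                        "n_meth": n_meth,
                        "n_unmeth": coverage - n_meth,
                        "context": contexts,
                        "trinucleotide": trinucs,
                    }
                )
            )

    methylomes = {
        tp: pd.concat(parts, ignore_index=True)[CYTOSINE_REPORT_COLUMNS]
        for tp, parts in frames.items()
    }

    # spike-in control: fully unmethylated up to the conversion error rate
    lam_pos, lam_strand, lam_ctx, lam_tri = _cytosine_sites(genome.lambda_sequence)
    lam_cov = np.maximum(rng.poisson(spec.coverage_mean, len(lam_pos)), 1)
    lam_meth = rng.binomial(lam_cov, 1.0 - spec.conversion_rate)
    lambda_calls = pd.DataFrame(
        {
            "chrom": "lambda",
            "pos": lam_pos + 1,
            "strand": lam_strand,
            "n_meth": lam_meth,
            "n_unmeth": lam_cov - lam_meth,
            "context": lam_ctx,
            "trinucleotide": lam_tri,
        }
    )[CYTOSINE_REPORT_COLUMNS]

    truth = GroundTruth(
        planted_umrs={tp: list(genome.umrs) for tp in spec.timepoints},
        planted_lmrs={tp: list(genome.lmrs) for tp in spec.timepoints},
        planted_dmrs=list(genome.dmrs),
        planted_motif_sites=list(genome.motif_sites),
        planted_edges=list(genome.edges),
        expression_truth={
            d.gene: {d.transition: "up" if d.direction == "hypo" else "down"}
            for d in genome.dmrs
        },
    )
    return methylomes, truth, lambda_calls


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    spec: SyntheticSpec,
    truth: GroundTruth,
    genome: SyntheticGenome,
    compliance: float | None = None,
) -> pd.DataFrame:
    """Expression table: gene, per-time-point RPKM, per-transition log2FC
    and adjusted P.

    Genes linked to planted hypo-DMRs are up-regulated across the DMR's
    transition, hyper-DMR genes down-regulated, each with probability
    ``compliance`` (spec default 0.9; at 1.0 anti-correlation is forced, at
    0.0 it is inverted everywhere).  Every TF used in planted edges has
    RPKM > 1 at all time points.
    """
    rng = np.random.default_rng(spec.seed + 2)
    comp = spec.compliance if compliance is None else compliance
    tps = spec.timepoints
    trans = spec.transitions

    tf_names = sorted({tf for tf, _, _ in truth.planted_edges}) or list(_TF_CONSENSUS)
    gene_names = [gm.name for gm in genome.gene_models]
    rows = []
    for name in gene_names + [t for t in tf_names if t not in gene_names]:
        is_tf = name in tf_names
        base = float(rng.uniform(5, 50)) if is_tf else float(rng.lognormal(1.2, 1.0))
        fcs: dict[str, float] = {}
        padjs: dict[str, float] = {}
        planted = truth.expression_truth.get(name, {})
        for tname, _, _ in trans:
            if tname in planted:
                magnitude = float(rng.uniform(1.0, 3.0))
                sign = 1.0 if planted[tname] == "up" else -1.0
                if rng.random() >= comp:
                    sign = -sign
                fcs[tname] = sign * magnitude
                padjs[tname] = 1e-4
            else:
                fcs[tname] = float(rng.normal(0.0, 0.15))
                padjs[tname] = float(rng.uniform(0.2, 1.0))
        rpkm = [max(base, 1.5) if is_tf else base]
        for tname, _, _ in trans:
            rpkm.append(rpkm[-1] * 2.0 ** fcs[tname])
        if is_tf:
            rpkm = [max(r, 1.5) for r in rpkm]
            for k, (tname, a, b) in enumerate(trans):
                fcs[tname] = float(np.log2(rpkm[b] / rpkm[a]))
        row: dict[str, object] = {"gene": name}
        for tp, r in zip(tps, rpkm):
            row[f"rpkm_{tp}"] = r
        for tname, _, _ in trans:
            row[f"log2fc_{tname}"] = fcs[tname]
            row[f"padj_{tname}"] = padjs[tname]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk dataset


def write_dataset(
    outdir: str | Path,
    spec: SyntheticSpec,
    genome: SyntheticGenome,
    methylomes: Mapping[str, pd.DataFrame],
    truth: GroundTruth,
    lambda_calls: pd.DataFrame,
    expression: pd.DataFrame,
) -> Path:
    """Write the full dataset under ``outdir`` with a parameter manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(genome.sequences, out / "genome.fa")
    write_fasta({"lambda": genome.lambda_sequence}, out / "lambda.fa")
    (out / "tracks").mkdir(exist_ok=True)
    for name, track in genome.tracks.items():
        write_bed(track, out / "tracks" / f"{name}.bed")
    for tp, calls in methylomes.items():
        write_cytosine_report(calls, out / f"calls_{tp}.tsv")
    write_cytosine_report(lambda_calls, out / "calls_lambda.tsv")
    (out / "truth").mkdir(exist_ok=True)
    write_bed(genome.umrs, out / "truth" / "umrs.bed")
    write_bed(genome.lmrs, out / "truth" / "lmrs.bed")
    with open(out / "truth" / "dmrs.tsv", "w") as fh:
        for d in truth.planted_dmrs:
            fh.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t"
                f"{d.transition}\t{d.direction}\t{d.tf}\t{d.gene}\n"
            )
    with open(out / "truth" / "edges.tsv", "w") as fh:
        for tf, gene, tname in truth.planted_edges:
            fh.write(f"{tf}\t{gene}\t{tname}\n")
    with open(out / "truth" / "motif_sites.tsv", "w") as fh:
        for iv, name in truth.planted_motif_sites:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
    write_interactions(genome.interactions, out / "interactions.tsv")
    expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    write_jaspar(genome.motifs, out / "motifs.jaspar")
    with open(out / "genes.tsv", "w") as fh:
        for gm in genome.gene_models:
            exons = ";".join(f"{s}-{e}" for s, e in gm.exons)
            fh.write(
                f"{gm.chrom}\t{gm.start}\t{gm.end}\t{gm.strand}\t{gm.name}\t{exons}\n"
            )
    manifest = {"spec": asdict(spec)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
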
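"""PWM motif scanning and region-set enrichment.

Transcription-factor binding preferences are modelled as position weight
matrices (PWMs) scored in log2 odds against a background nucleotide
distribution.  Region sets are tested for motif enrichment against matched
background regions with a hypergeometric region-hit test (a region "hits" a
motif if it contains at least one scan hit), and candidate factors are
filtered for expression (RPKM > 1 by default) so only plausibly active TFs
survive.

JASPAR text PFMs are read through Bio.motifs where possible, with a
fallback for the plain (letter-less) four-row dialect.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval

__all__ = [
    "PWMotif",
    "MotifHit",
    "EnrichmentResult",
    "read_jaspar",
    "write_jaspar",
    "scan",
    "enrich",
    "screen_enrichment",
    "build_background",
]

_BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(_BASES)}
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PWMotif:
    """A position weight matrix with log-odds scoring.

    ``matrix`` holds per-position base probabilities (rows sum to 1),
    ``background`` the genomic base composition the odds are taken against.
    ``min_score`` is the log2-odds hit threshold; when None, scanning
    defaults to 80% of the maximal achievable score (a JASPAR-style
    relative-score convention).
    """

    name: str
    matrix: np.ndarray  # (L, 4), A C G T
    background: np.ndarray = None  # type: ignore[assignment]
    min_score: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.background is None:
            self.background = UNIFORM_BG.copy()
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must have shape (L, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif must span at least 4 positions")
        sums = self.matrix.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError(f"motif {self.name}: zero-sum column")
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"motif {self.name}: position probabilities must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.8,
        min_score: float | None = None,
    ) -> "PWMotif":
        """Build a PWM from a count matrix; the pseudocount is split across
        bases in proportion to the background frequencies."""
        counts = np.asarray(counts, dtype=float)
        bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
        col_tot = counts.sum(axis=1, keepdims=True)
        if np.any(col_tot <= 0):
            raise ValueError(f"motif {name}: zero-sum column")
        probs = (counts + pseudocount * bg) / (col_tot + pseudocount)
        return cls(name, probs, bg.copy(), min_score)

    def log_odds(self) -> np.ndarray:
        """(L, 5) log2-odds matrix; the fifth column (N) contributes 0."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.matrix / self.background)
        lo[np.isneginf(lo)] = -np.inf
        return np.column_stack([lo, np.zeros(len(self))])

    def max_score(self) -> float:
        with np.errstate(divide="ignore"):
            return float(np.log2(self.matrix / self.background).max(axis=1).sum())

    def effective_min_score(self) -> float:
        if self.min_score is not None:
            return self.min_score
        return 0.8 * self.max_score()

    def reverse_complement(self) -> "PWMotif":
        rc = self.matrix[::-1, ::-1].copy()
        return PWMotif(self.name, rc, self.background[::-1].copy(), self.min_score)


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based start of the match on the forward strand
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    enc = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _ENC.items():
        enc[arr == ord(base)] = code
    return enc


def scan(
    sequence: str,
    motif: PWMotif,
    min_score: float | None = None,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All positions where the motif's log2-odds score reaches threshold.

    Both strands are scanned; a minus-strand hit's position is the start of
    the matched window on the forward strand, so reverse-complementing the
    sequence mirrors the hit set with identical scores.  N bases score as
    background (zero log-odds contribution).
    """
    threshold = min_score if min_score is not None else motif.effective_min_score()
    L = len(motif)
    if len(sequence) < L:
        return []
    enc = _encode(sequence)
    n_win = len(enc) - L + 1
    hits: list[MotifHit] = []
    strands = [("+", motif)] + ([("-", motif.reverse_complement())] if both_strands else [])
    for strand, m in strands:
        lo = m.log_odds()
        scores = np.zeros(n_win)
        for j in range(L):
            scores += lo[j, enc[j : j + n_win]]
        for pos in np.nonzero(scores >= threshold)[0]:
            hits.append(MotifHit(int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# JASPAR text I/O


def read_jaspar(path: str | Path) -> list[PWMotif]:
    """Read JASPAR-format PFMs (bracketed "A [ ... ]" rows or plain 4-row)."""
    text = Path(path).read_text()
    try:
        from Bio import motifs as bio_motifs

        parsed = bio_motifs.parse(_stdio.StringIO(text), "jaspar")
        out = []
        for m in parsed:
            counts = np.column_stack([m.counts[b] for b in _BASES])
            name = m.name or m.matrix_id or "motif"
            out.append(PWMotif.from_counts(str(name), counts))
        if out:
            return out
    except Exception:
        pass
    return _read_plain_pfm(text)


def _read_plain_pfm(text: str) -> list[PWMotif]:
    out: list[PWMotif] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, name
        if name is not None and rows:
            if len(rows) != 4:
                raise ValueError(f"motif {name}: expected 4 count rows, got {len(rows)}")
            out.append(PWMotif.from_counts(name, np.array(rows).T))
        rows = []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0]
        else:
            rows.append([float(x) for x in line.replace("[", " ").replace("]", " ").split() if x not in "ACGT"])
    flush()
    if not out:
        raise ValueError("no motifs found")
    return out


def write_jaspar(motifs: Sequence[PWMotif], path: str | Path, scale: int = 100) -> None:
    """Write motifs as JASPAR bracketed count matrices (probabilities scaled)."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.name}\n")
            counts = np.rint(m.matrix * scale).astype(int)
            for i, base in enumerate(_BASES):
                row = " ".join(str(c) for c in counts[:, i])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Enrichment


@dataclass
class EnrichmentResult:
    motif: str
    n_fg_hit: int
    n_fg: int
    n_bg_hit: int
    n_bg: int
    p_value: float
    q_value: float = float("nan")
    expressed: bool | None = None


def _region_seq(genome: Mapping[str, str], region: GenomicInterval) -> str:
    return genome[region.chrom][region.start : region.end]


def enrich(
    fg_regions: Sequence[GenomicInterval],
    bg_regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    motifs: Sequence[PWMotif],
    expression: pd.DataFrame | None = None,
    rpkm_min: float = 1.0,
    min_score: float | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric motif enrichment of foreground vs background regions.

    With the pooled region set as the population and the foreground as the
    draw, the upper-tail probability P(X >= n_fg_hit) tests over-
    representation of motif-hit regions in the foreground.  q-values are BH
    across motifs.  ``expression`` (columns: gene + rpkm_* per time point)
    sets the expressed flag to max RPKM > ``rpkm_min`` for the motif's
    factor; missing factors are flagged not-expressed.
    """
    if not bg_regions:
        raise ValueError("enrichment is undefined without background regions")
    fg_seqs = [_region_seq(genome, r) for r in fg_regions]
    bg_seqs = [_region_seq(genome, r) for r in bg_regions]

    rpkm_cols = (
        [c for c in expression.columns if c.startswith("rpkm")]
        if expression is not None
        else []
    )
    results: list[EnrichmentResult] = []
    for m in motifs:
        fg_hit = sum(1 for s in fg_seqs if scan(s, m, min_score))
        bg_hit = sum(1 for s in bg_seqs if scan(s, m, min_score))
        N = len(fg_seqs) + len(bg_seqs)
        K = fg_hit + bg_hit
        n = len(fg_seqs)
        p = float(stats.hypergeom.sf(fg_hit - 1, N, K, n)) if K else 1.0
        expressed: bool | None = None
        if expression is not None:
            row = expression[expression["gene"] == m.name]
            expressed = bool(
                len(row) and float(row[rpkm_cols].to_numpy().max()) > rpkm_min
            )
        results.append(
            EnrichmentResult(m.name, fg_hit, len(fg_seqs), bg_hit, len(bg_seqs), min(p, 1.0), expressed=expressed)
        )
    qvals = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    results.sort(key=lambda r: r.p_value)
    return results


def screen_enrichment(
    results: Sequence[EnrichmentResult],
    alpha: float = 1e-10,
    require_expressed: bool = True,
) -> list[str]:
    """Motifs passing the enrichment screen: p strictly below ``alpha`` and,
    when required, the factor expressed (RPKM above threshold).

    The default alpha is the stringent region-screen gate; network
    construction uses a more permissive 0.01 on the DMR sets.
    """
    out = []
    for r in results:
        if r.p_value >= alpha:
            continue
        if require_expressed and not r.expressed:
            continue
        out.append(r.motif)
    return out


def build_background(
    fg_regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    n_per_fg: int = 2,
    seed: int = 0,
    gc_tol: float = 0.05,
    max_tries: int = 500,
) -> list[GenomicInterval]:
    """Length- and GC-matched random background regions avoiding the foreground.

    For each foreground region, ``n_per_fg`` random regions of identical
    length are drawn whose GC content is within ``gc_tol`` (as a fraction)
    of the foreground region's; candidates overlapping any foreground region
    are rejected.  If matching fails after ``max_tries`` draws the tolerance
    is doubled with a warning.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    sizes = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights = sizes / sizes.sum()

    fg_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in fg_regions:
        fg_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))

    def gc_frac(seq: str) -> float:
        if not seq:
            return 0.0
        return (seq.count("G") + seq.count("C")) / len(seq)

    out: list[GenomicInterval] = []
    for r in fg_regions:
        target_gc = gc_frac(_region_seq(genome, r))
        length = len(r)
        for _ in range(n_per_fg):
            tol = gc_tol
            placed = False
            tries = 0
            while not placed:
                tries += 1
                if tries > max_tries:
                    tol *= 2
                    tries = 0
                    warnings.warn(
                        f"relaxing GC tolerance to {tol:.3f} for a background "
                        f"region matched to {r.chrom}:{r.start}-{r.end}"
                    )
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                limit = len(genome[chrom]) - length
                if limit <= 0:
                    continue
                start = int(rng.integers(0, limit))
                end = start + length
                if any(
                    s < end and start < e for s, e in fg_by_chrom.get(chrom, [])
                ):
                    continue
                if abs(gc_frac(genome[chrom][start:end]) - target_gc) > tol:
                    continue
                out.append(GenomicInterval(chrom, start, end))
                placed = True
    return out
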
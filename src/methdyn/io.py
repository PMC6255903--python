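"""Reading and writing of methylome-adjacent formats, plus library QC.

This module owns the on-disk dialects used throughout the package:

* Bismark-style per-cytosine report TSVs (1-based cytosine positions,
  strand-resolved methylated/unmethylated read counts, sequence context),
* BED3-BED6 interval tracks (0-based, half-open),
* FASTA genomes (indexed access through :mod:`pyfaidx`),

and the per-library QC statistics: fold coverage, bisulfite conversion rate
estimated from an unmethylated spike-in control, and the composition of
methylated cytosines across the CG / CHG / CHH sequence contexts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenomicInterval",
    "QCReport",
    "classify_context",
    "revcomp",
    "read_genome",
    "write_fasta",
    "read_cytosine_report",
    "write_cytosine_report",
    "merge_symmetric_cpg",
    "filter_coverage",
    "methylation_levels",
    "qc_report",
    "read_bed",
    "write_bed",
]

CYTOSINE_REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "n_meth",
    "n_unmeth",
    "context",
    "trinucleotide",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MalformedInputError(ValueError):
    """Raised when an on-disk file violates its dialect (with line numbers)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval, sortable by (chrom, start, end).

    ``name``, ``score`` and ``strand`` mirror the optional BED columns and
    are ``None`` when absent.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if on different chroms)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        return self.overlap_bp(other) >= min_bp


def classify_context(trinucleotide: str) -> str:
    """Classify a cytosine's sequence context from its strand-local 3-mer.

    The 3-mer starts with the cytosine itself.  A G in second position gives
    CG; otherwise a G in third position gives CHG; otherwise CHH (H is A, T
    or C).  An N in a position that would decide the call yields
    ``"ambiguous"``, which downstream analyses exclude.
    """
    tri = trinucleotide.upper()
    if len(tri) != 3 or any(b not in "ACGTN" for b in tri):
        raise ValueError(f"not a valid trinucleotide: {trinucleotide!r}")
    if tri[0] != "C":
        raise ValueError(f"trinucleotide must start with C: {trinucleotide!r}")
    if tri[1] == "N":
        return "ambiguous"
    if tri[1] == "G":
        return "CG"
    if tri[2] == "N":
        return "ambiguous"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome into memory as ``{chrom: uppercase sequence}``.

    Uses pyfaidx for indexed access, so an accompanying ``.fai`` is created
    next to the file when absent.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Cytosine reports


def read_cytosine_report(
    path: str | Path, genome: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a Bismark-style cytosine report TSV into a DataFrame.

    Columns: chrom, pos (1-based position of the cytosine on its strand),
    strand (+/-), n_meth, n_unmeth, context, trinucleotide.  The file must be
    sorted by (chrom, pos); violations and malformed rows are reported with
    their 1-based line number.  When ``genome`` is given, each row's
    trinucleotide is cross-checked against the sequence.
    """
    try:
        df = pd.read_csv(
            str(path),
            sep="\t",
            names=CYTOSINE_REPORT_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
            header=None,
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CYTOSINE_REPORT_COLUMNS)
    if df.empty:
        return df

    for col in ("pos", "n_meth", "n_unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            raise MalformedInputError(
                f"{path}: non-integer {col} at line {bad.idxmax() + 1}"
            )
        df[col] = vals.astype(int)

    neg = (df["n_meth"] < 0) | (df["n_unmeth"] < 0)
    if neg.any():
        raise MalformedInputError(
            f"{path}: negative read count at line {neg.idxmax() + 1}"
        )
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise MalformedInputError(
            f"{path}: invalid strand at line {bad_strand.idxmax() + 1}"
        )

    # sortedness: grouped by chrom, non-decreasing pos within each chrom
    chrom_change = df["chrom"].ne(df["chrom"].shift())
    seen: set[str] = set()
    for i, (chrom, is_new) in enumerate(zip(df["chrom"], chrom_change)):
        if is_new:
            if chrom in seen:
                raise MalformedInputError(
                    f"{path}: unsorted input, chromosome {chrom} re-appears at line {i + 1}"
                )
            seen.add(chrom)
    pos_bad = (~chrom_change) & (df["pos"] < df["pos"].shift())
    if pos_bad.any():
        raise MalformedInputError(
            f"{path}: unsorted input at line {pos_bad.idxmax() + 1}"
        )

    # context must be the pure function of the trinucleotide
    expected = df["trinucleotide"].map(_classify_cached)
    mismatch = expected != df["context"]
    if mismatch.any():
        i = int(mismatch.idxmax())
        raise MalformedInputError(
            f"{path}: context/trinucleotide mismatch at line {i + 1}: "
            f"{df['trinucleotide'].iat[i]!r} implies {expected.iat[i]}, "
            f"found {df['context'].iat[i]!r}"
        )

    if genome is not None:
        _crosscheck_trinucleotides(df, genome, str(path))
    return df


_CLASSIFY_CACHE: dict[str, str] = {}


def _classify_cached(tri: str) -> str:
    try:
        return _CLASSIFY_CACHE[tri]
    except KeyError:
        try:
            ctx = classify_context(tri)
        except ValueError:
            ctx = "<invalid>"
        _CLASSIFY_CACHE[tri] = ctx
        return ctx


def _crosscheck_trinucleotides(
    df: pd.DataFrame, genome: Mapping[str, str], path: str
) -> None:
    for i, (chrom, pos, strand, tri) in enumerate(
        zip(df["chrom"], df["pos"], df["strand"], df["trinucleotide"])
    ):
        seq = genome.get(chrom)
        if seq is None:
            raise MalformedInputError(
                f"{path}: unknown chromosome {chrom!r} at line {i + 1}"
            )
        j = pos - 1
        if strand == "+":
            ref = (seq[j : j + 3] + "NN")[:3]
        else:
            ref = revcomp(seq[max(0, j - 2) : j + 1].rjust(3, "N"))
        if ref != tri:
            raise MalformedInputError(
                f"{path}: trinucleotide mismatch at line {i + 1}: "
                f"reference {ref!r}, reported {tri!r}"
            )


def write_cytosine_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(str(path), sep="\t", header=False, index=False, columns=CYTOSINE_REPORT_COLUMNS)


def merge_symmetric_cpg(calls: pd.DataFrame) -> pd.DataFrame:
    """Pool plus/minus strand counts of each symmetric CpG dyad.

    Counts are summed at the plus-strand cytosine's position (the minus
    strand C of a dyad sits one base downstream on the plus-strand axis).
    Non-CpG calls pass through unchanged; total read counts are conserved.
    """
    if calls.empty:
        return calls.copy()
    cg = calls[calls["context"] == "CG"].copy()
    rest = calls[calls["context"] != "CG"]
    if cg.empty:
        return calls.copy()

    cg["_dyad"] = np.where(cg["strand"] == "+", cg["pos"], cg["pos"] - 1)
    # a plus-strand observation carries the dyad's 3-mer; a lone minus call
    # only pins the first two bases (CG by definition), third unknown
    cg["_tri"] = cg["trinucleotide"].where(cg["strand"] == "+")
    grouped = cg.groupby(["chrom", "_dyad"], sort=False)
    pooled = grouped.agg(
        n_meth=("n_meth", "sum"),
        n_unmeth=("n_unmeth", "sum"),
        trinucleotide=("_tri", "first"),
    ).reset_index()
    pooled["trinucleotide"] = pooled["trinucleotide"].fillna("CGN")
    pooled = pooled.rename(columns={"_dyad": "pos"})
    pooled["strand"] = "+"
    pooled["context"] = "CG"
    out = pd.concat([pooled[CYTOSINE_REPORT_COLUMNS], rest])
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return out.reset_index(drop=True)


def filter_coverage(calls: pd.DataFrame, min_coverage: int = 5) -> pd.DataFrame:
    """Keep calls with at least ``min_coverage`` reads (default 5)."""
    cov = calls["n_meth"] + calls["n_unmeth"]
    return calls[cov >= min_coverage].reset_index(drop=True)


def methylation_levels(calls: pd.DataFrame) -> np.ndarray:
    """Per-call methylation fraction n_meth / (n_meth + n_unmeth).

    NaN where coverage is zero (the level is undefined there).
    """
    cov = (calls["n_meth"] + calls["n_unmeth"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lv = calls["n_meth"].to_numpy(dtype=float) / cov
    return lv


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    """Library-level QC statistics.

    fold_coverage is in units of genome equivalents (X).  conversion_rate is
    the bisulfite conversion efficiency estimated from the unmethylated
    spike-in control, or None when no control was provided (never silently
    1.0).  meth_fraction_by_context gives, of all cytosines called
    methylated, the fraction in each context; the three fractions sum to 1
    whenever any methylated cytosine exists.
    """

    fold_coverage: float
    conversion_rate: float | None
    n_calls_by_context: dict[str, int]
    meth_fraction_by_context: dict[str, float]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def qc_report(
    calls: pd.DataFrame,
    genome_size: int,
    n_aligned_reads: int,
    read_length: int = 100,
    lambda_calls: pd.DataFrame | None = None,
    use_aligned_bases: bool = True,
    meth_criterion: str = "auto",
    level_threshold: float = 0.1,
    q_threshold: float = 0.05,
) -> QCReport:
    """Compute library QC statistics from a cytosine call table.

    Fold coverage defaults to aligned bases over genome size
    (``n_aligned_reads * read_length / genome_size``); set
    ``use_aligned_bases=False`` for the bare read-count quotient.

    A cytosine counts as methylated, for the context-composition statistic,
    either by a per-site binomial test of its methylated count against the
    conversion-error rate (BH-corrected, q < ``q_threshold``) when a spike-in
    control is available, or by a simple level threshold otherwise
    (``meth_criterion`` = "auto" | "binomial" | "level").
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    scale = read_length if use_aligned_bases else 1
    fold_coverage = n_aligned_reads * scale / genome_size

    conversion_rate: float | None = None
    if lambda_calls is not None and len(lambda_calls):
        tot = int(lambda_calls["n_meth"].sum() + lambda_calls["n_unmeth"].sum())
        if tot > 0:
            conversion_rate = 1.0 - float(lambda_calls["n_meth"].sum()) / tot

    contexts = ("CG", "CHG", "CHH")
    n_calls = {c: int((calls["context"] == c).sum()) for c in contexts}

    covered = calls[(calls["n_meth"] + calls["n_unmeth"]) > 0]
    if meth_criterion == "binomial" and conversion_rate is None:
        raise ValueError("binomial criterion requires a spike-in control table")
    use_binomial = meth_criterion == "binomial" or (
        meth_criterion == "auto" and conversion_rate is not None
    )
    if len(covered) == 0:
        is_meth = np.zeros(0, dtype=bool)
    elif use_binomial:
        err = max(1.0 - conversion_rate, 1e-12)  # type: ignore[operator]
        cov = (covered["n_meth"] + covered["n_unmeth"]).to_numpy()
        p = stats.binom.sf(covered["n_meth"].to_numpy() - 1, cov, err)
        from statsmodels.stats.multitest import multipletests

        is_meth = multipletests(p, alpha=q_threshold, method="fdr_bh")[0]
        is_meth &= covered["n_meth"].to_numpy() > 0
    else:
        is_meth = methylation_levels(covered) > level_threshold

    meth = covered[is_meth] if len(covered) else covered
    n_meth_total = int(sum((meth["context"] == c).sum() for c in contexts))
    if n_meth_total:
        frac = {c: float((meth["context"] == c).sum()) / n_meth_total for c in contexts}
    else:
        frac = {c: 0.0 for c in contexts}
    return QCReport(
        fold_coverage=fold_coverage,
        conversion_rate=conversion_rate,
        n_calls_by_context=n_calls,
        meth_fraction_by_context=frac,
    )


# ---------------------------------------------------------------------------
# BED


def _format_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(float(score))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3-BED6 into a list of intervals (0-based half-open kept as-is)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise MalformedInputError(f"{path}: fewer than 3 fields at line {lineno}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise MalformedInputError(
                    f"{path}: non-integer coordinate at line {lineno}"
                ) from exc
            if start >= end:
                raise MalformedInputError(
                    f"{path}: start >= end at line {lineno} ({start} >= {end})"
                )
            name = parts[3] if len(parts) > 3 else None
            score = float(parts[4]) if len(parts) > 4 else None
            strand = parts[5] if len(parts) > 5 else None
            out.append(GenomicInterval(chrom, start, end, name, score, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED, emitting only the trailing fields present."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            tail = []
            if iv.strand is not None:
                tail = [
                    iv.name if iv.name is not None else ".",
                    _format_score(iv.score) if iv.score is not None else "0",
                    iv.strand,
                ]
            elif iv.score is not None:
                tail = [iv.name if iv.name is not None else ".", _format_score(iv.score)]
            elif iv.name is not None:
                tail = [iv.name]
            fh.write("\t".join(fields + tail) + "\n")


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "name": [iv.name for iv in intervals],
            "score": [iv.score for iv in intervals],
            "strand": [iv.strand for iv in intervals],
        }
    )
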
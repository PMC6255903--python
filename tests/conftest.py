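"""Shared fixtures: a small synthetic study and call-table builders."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdyn.io import CYTOSINE_REPORT_COLUMNS
from methdyn.synthetic import (
    GroundTruth,
    SyntheticGenome,
    SyntheticSpec,
    generate_expression,
    generate_genome,
    generate_methylomes,
)

TINY_SPEC_KWARGS = dict(
    genome_length=150_000,
    n_umr=4,
    n_lmr=8,
    n_dmr=4,
    n_motif_planted=6,
    n_vista=3,
    n_extra_genes=3,
    seed=7,
)


@dataclass
class TinyStudy:
    spec: SyntheticSpec
    genome: SyntheticGenome
    methylomes: dict[str, pd.DataFrame]
    truth: GroundTruth
    lambda_calls: pd.DataFrame
    expression: pd.DataFrame


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    return SyntheticSpec(**TINY_SPEC_KWARGS)


@pytest.fixture(scope="session")
def tiny_study(tiny_spec: SyntheticSpec) -> TinyStudy:
    genome = generate_genome(tiny_spec)
    methylomes, truth, lambda_calls = generate_methylomes(tiny_spec, genome)
    expression = generate_expression(tiny_spec, truth, genome)
    return TinyStudy(tiny_spec, genome, methylomes, truth, lambda_calls, expression)


def make_calls(
    levels: list[float],
    coverage: int = 20,
    chrom: str = "chr1",
    start: int = 1000,
    spacing: int = 25,
    context: str = "CG",
) -> pd.DataFrame:
    """Deterministic CG call table: one pooled-dyad call per level.

    Counts are exact (n_meth = round(level * coverage)), so the emitted
    methylation levels equal the requested ones up to rounding.
    """
    tri = {"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}[context]
    rows = []
    for i, level in enumerate(levels):
        n_meth = int(round(level * coverage))
        rows.append(
            {
                "chrom": chrom,
                "pos": start + i * spacing,
                "strand": "+",
                "n_meth": n_meth,
                "n_unmeth": coverage - n_meth,
                "context": context,
                "trinucleotide": tri,
            }
        )
    return pd.DataFrame(rows, columns=CYTOSINE_REPORT_COLUMNS)


def brute_force_signed_rank(differences) -> float:
    """Independent oracle: enumerate all sign assignments (n <= ~14).

    Two-sided p = share of assignments whose positive-rank sum deviates
    from its mean at least as much as observed.  Integer arithmetic on
    doubled midranks keeps the comparison exact.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    r2 = np.rint(2 * stats.rankdata(np.abs(d))).astype(int)
    total = int(r2.sum())
    obs_dev = abs(2 * int(r2[d > 0].sum()) - total)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w2 = int(sum(r for r, s in zip(r2, signs) if s))
        if abs(2 * w2 - total) >= obs_dev:
            count += 1
    return count / 2**n
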
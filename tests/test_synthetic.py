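"""Synthetic study generator: determinism, planted structure, invariants."""

import numpy as np
import pytest

from methdyn.io import methylation_levels, write_fasta
from methdyn.synthetic import (
    InvalidSpecError,
    SyntheticSpec,
    generate_expression,
    generate_genome,
    generate_methylomes,
)

from conftest import TINY_SPEC_KWARGS


def small_spec(**overrides):
    kwargs = {**TINY_SPEC_KWARGS, **overrides}
    return SyntheticSpec(**kwargs)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("genome_length", 0),
            ("genome_length", -5),
            ("umr_level", 0.2),
            ("lmr_level", 0.6),
            ("lmr_level", 0.05),
            ("background_level", 0.4),
            ("dmr_delta", 0.2),
            ("n_umr", -1),
        ],
    )
    def test_invariant_violations_rejected(self, field, value):
        with pytest.raises(InvalidSpecError):
            small_spec(**{field: value})

    def test_genome_too_small_for_layout(self):
        with pytest.raises(InvalidSpecError, match="too small"):
            generate_genome(small_spec(genome_length=20_000))


class TestGenerateGenome:
    def test_deterministic_fasta_bytes(self, tmp_path):
        a = generate_genome(small_spec(seed=1))
        b = generate_genome(small_spec(seed=1))
        write_fasta(a.sequences, tmp_path / "a.fa")
        write_fasta(b.sequences, tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_chromosome_count_and_length(self):
        spec = small_spec(
            n_chroms=2, genome_length=50_000, n_umr=2, n_lmr=2, n_dmr=2, n_extra_genes=1
        )
        genome = generate_genome(spec)
        assert len(genome.sequences) == 2
        assert all(len(s) == 50_000 for s in genome.sequences.values())

    def test_full_dhs_cover_fraction(self):
        genome = generate_genome(small_spec(dhs_cover_fraction=1.0))
        dhs = genome.tracks["dhs"]
        for lmr in genome.lmrs:
            assert any(lmr.overlaps(d) for d in dhs)

    def test_planted_regions_disjoint_and_in_bounds(self):
        spec = small_spec()
        genome = generate_genome(spec)
        regions = sorted(
            genome.umrs + genome.lmrs + [d.interval for d in genome.dmrs]
        )
        for r in regions:
            assert 0 <= r.start < r.end <= spec.genome_length
        for a, b in zip(regions, regions[1:]):
            if a.chrom == b.chrom:
                assert b.start - a.end >= 300  # separated by background

    def test_motif_sites_inside_planted_regions(self):
        genome = generate_genome(small_spec())
        planted = genome.lmrs + [d.interval for d in genome.dmrs]
        for site, name in genome.motif_sites:
            assert any(
                site.chrom == r.chrom and r.start <= site.start and site.end <= r.end
                for r in planted
            )
            consensus = genome.sequences[site.chrom][site.start : site.end]
            assert name in ("Tfa", "Tfb", "Ctcf")
            assert set(consensus) <= set("ACGT")


class TestGenerateMethylomes:
    def test_deterministic_tables(self):
        spec = small_spec(seed=3)
        g = generate_genome(spec)
        a, _, _ = generate_methylomes(spec, g)
        b, _, _ = generate_methylomes(spec, g)
        for tp in spec.timepoints:
            assert a[tp].equals(b[tp])

    def test_zero_mch_rate_gives_zero_non_cpg_methylation(self):
        spec = small_spec(mch_rate_by_timepoint=(0.0, 0.0, 0.0))
        g = generate_genome(spec)
        methylomes, _, _ = generate_methylomes(spec, g)
        for calls in methylomes.values():
            non_cpg = calls[calls["context"] != "CG"]
            assert (non_cpg["n_meth"] == 0).all()

    def test_umr_empirical_mean_below_threshold_at_high_coverage(self):
        spec = small_spec(coverage_mean=1000.0)
        g = generate_genome(spec)
        methylomes, _, _ = generate_methylomes(spec, g)
        calls = methylomes[spec.timepoints[0]]
        cg = calls[calls["context"] == "CG"]
        levels = methylation_levels(cg)
        pos = cg["pos"].to_numpy()
        for umr in g.umrs:
            mask = (
                (cg["chrom"] == umr.chrom).to_numpy()
                & (pos >= umr.start + 1)
                & (pos <= umr.end)
            )
            assert 0.0 <= float(levels[mask].mean()) <= 0.10

    def test_region_means_converge_to_spec_levels(self, tiny_study):
        """Empirical means within 3 binomial SEs of the planted levels."""
        spec = tiny_study.spec
        calls = tiny_study.methylomes[spec.timepoints[0]]
        cg = calls[calls["context"] == "CG"]
        levels = methylation_levels(cg)
        pos = cg["pos"].to_numpy()

        def region_mean(region):
            mask = (
                (cg["chrom"] == region.chrom).to_numpy()
                & (pos >= region.start + 1)
                & (pos <= region.end)
            )
            return float(levels[mask].mean()), int(mask.sum())

        for region, level in [(r, spec.lmr_level) for r in tiny_study.genome.lmrs] + [
            (r, spec.umr_level) for r in tiny_study.genome.umrs
        ]:
            mean, n = region_mean(region)
            se = np.sqrt(level * (1 - level) / (n * spec.coverage_mean))
            assert abs(mean - level) <= 3 * se + 0.01

    def test_planted_dmr_delta_matches_spec(self, tiny_study):
        """Emitted count tables reproduce the planted delta within 0.10."""
        spec = tiny_study.spec
        tp_index = {tp: i for i, tp in enumerate(spec.timepoints)}
        tables = {
            tp: tiny_study.methylomes[tp][
                tiny_study.methylomes[tp]["context"] == "CG"
            ]
            for tp in spec.timepoints
        }
        for d in tiny_study.truth.planted_dmrs:
            k = [t for t in spec.transitions if t[0] == d.transition][0]
            tp_a, tp_b = spec.timepoints[k[1]], spec.timepoints[k[2]]
            means = {}
            for tp in (tp_a, tp_b):
                calls = tables[tp]
                pos = calls["pos"].to_numpy()
                mask = (
                    (calls["chrom"] == d.interval.chrom).to_numpy()
                    & (pos >= d.interval.start + 1)
                    & (pos <= d.interval.end)
                )
                means[tp] = float(methylation_levels(calls)[mask].mean())
            delta = means[tp_b] - means[tp_a]
            expected = spec.dmr_delta if d.direction == "hyper" else -spec.dmr_delta
            assert abs(delta - expected) <= 0.10

    def test_lambda_control_mostly_unmethylated(self, tiny_study):
        lam = tiny_study.lambda_calls
        rate = lam["n_meth"].sum() / (lam["n_meth"] + lam["n_unmeth"]).sum()
        assert rate == pytest.approx(1 - tiny_study.spec.conversion_rate, abs=0.005)


class TestGenerateExpression:
    def test_full_compliance_forces_anticorrelation(self):
        spec = small_spec(compliance=1.0)
        g = generate_genome(spec)
        _, truth, _ = generate_methylomes(spec, g)
        expr = generate_expression(spec, truth, g)
        for gene, by_trans in truth.expression_truth.items():
            row = expr[expr["gene"] == gene].iloc[0]
            for tname, direction in by_trans.items():
                assert (row[f"log2fc_{tname}"] > 0) == (direction == "up")

    def test_planted_tfs_expressed_at_all_timepoints(self, tiny_study):
        expr = tiny_study.expression
        rpkm_cols = [c for c in expr.columns if c.startswith("rpkm_")]
        for tf, _, _ in tiny_study.truth.planted_edges:
            row = expr[expr["gene"] == tf].iloc[0]
            assert (row[rpkm_cols] > 1).all()

    def test_deterministic(self, tiny_study):
        again = generate_expression(
            tiny_study.spec, tiny_study.truth, tiny_study.genome
        )
        assert again.equals(tiny_study.expression)
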
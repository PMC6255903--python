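"""PWM scanning, JASPAR IO, enrichment statistics, background matching."""

import numpy as np
import pytest

from methdyn.io import GenomicInterval, revcomp
from methdyn.motifs import (
    PWMotif,
    build_background,
    enrich,
    read_jaspar,
    scan,
    write_jaspar,
)


def consensus_motif(consensus, pseudocount=0.0):
    matrix = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        matrix[i, "ACGT".index(b)] = 1.0
    if pseudocount:
        matrix = (matrix + pseudocount / 4) / (1 + pseudocount)
    return PWMotif("test", matrix)


def brute_force_scan(sequence, motif, threshold):
    """Position-by-position oracle over both strands."""
    hits = []
    L = len(motif)
    for strand, m in (("+", motif), ("-", motif.reverse_complement())):
        for pos in range(len(sequence) - L + 1):
            score = 0.0
            for j, base in enumerate(sequence[pos : pos + L]):
                if base == "N":
                    continue
                k = "ACGT".index(base)
                score += np.log2(m.matrix[j, k] / m.background[k])
            if score >= threshold:
                hits.append((pos, strand, pytest.approx(score)))
    return hits


class TestScan:
    def test_consensus_scores_two_bits_per_position(self):
        """Probability-1 motif on its own consensus, uniform background."""
        consensus = "ACGTAC"
        motif = consensus_motif(consensus)
        hits = scan(consensus, motif, min_score=2 * len(consensus) - 1e-9)
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(2 * len(consensus))

    def test_sequence_shorter_than_motif(self):
        assert scan("ACG", consensus_motif("ACGTAC")) == []

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 300)) + "GACGTAGG" + "".join(
            rng.choice(list("ACGT"), 100)
        )
        motif = consensus_motif("GACGTAGG", pseudocount=0.1)
        fwd = scan(seq, motif)
        rev = scan(revcomp(seq), motif)
        assert len(fwd) == len(rev) > 0
        L = len(motif)
        mirrored = sorted(
            (len(seq) - L - h.position, {"+": "-", "-": "+"}[h.strand]) for h in rev
        )
        assert sorted((h.position, h.strand) for h in fwd) == mirrored
        assert sorted(round(h.score, 9) for h in fwd) == sorted(
            round(h.score, 9) for h in rev
        )

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGTN"), 500, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        motif = consensus_motif("TGACGT", pseudocount=0.4)
        threshold = 0.6 * motif.max_score()
        hits = scan(seq, motif, min_score=threshold)
        oracle = brute_force_scan(seq, motif, threshold)
        assert [(h.position, h.strand, h.score) for h in hits] == sorted(oracle)

    def test_zero_sum_column_rejected(self):
        with pytest.raises(ValueError, match="zero-sum|sum"):
            PWMotif.from_counts("bad", np.zeros((4, 4)))


class TestJasparIO:
    def test_bracketed_round_trip(self, tmp_path):
        motif = PWMotif.from_counts(
            "Tfx", np.array([[97, 1, 1, 1], [1, 97, 1, 1], [1, 1, 97, 1], [1, 1, 1, 97]])
        )
        write_jaspar([motif], tmp_path / "m.jaspar")
        (back,) = read_jaspar(tmp_path / "m.jaspar")
        assert back.name == "Tfx"
        assert np.allclose(back.matrix, motif.matrix, atol=0.02)

    def test_plain_four_row_dialect(self, tmp_path):
        (tmp_path / "plain.pfm").write_text(
            ">M1\n8 0 0 8\n0 8 0 0\n0 0 8 0\n0 0 0 8\n"
        )
        (motif,) = read_jaspar(tmp_path / "plain.pfm")
        assert motif.name == "M1"
        assert len(motif) == 4


class TestEnrich:
    def setup_population(self):
        """4 fg regions (3 with motif), 16 bg regions (1 with motif)."""
        rng = np.random.default_rng(23)
        consensus = "TTGACGTCAA"
        chunks = []
        regions = []
        cursor = 0
        for i in range(20):
            body = "".join(rng.choice(list("ACGT"), 100, p=[0.3, 0.2, 0.2, 0.3]))
            if i in (0, 1, 2, 4):  # 3 of the first 4 (fg) + 1 bg
                body = body[:40] + consensus + body[50:]
            chunks.append(body)
            regions.append(GenomicInterval("chr1", cursor, cursor + 100))
            cursor += 100
        genome = {"chr1": "".join(chunks)}
        motif = consensus_motif(consensus, pseudocount=0.04)
        # confirm planted hit pattern before testing the statistic
        flags = [bool(scan(genome["chr1"][r.start : r.end], motif)) for r in regions]
        assert flags == [i in (0, 1, 2, 4) for i in range(20)]
        return genome, regions, motif

    def test_hypergeometric_example(self):
        genome, regions, motif = self.setup_population()
        (result,) = enrich(regions[:4], regions[4:], genome, [motif])
        assert (result.n_fg_hit, result.n_fg, result.n_bg_hit, result.n_bg) == (
            3,
            4,
            1,
            16,
        )
        assert result.p_value == pytest.approx(65 / 4845)

    def test_absent_motif_p_one(self):
        genome, regions, _ = self.setup_population()
        absent = consensus_motif("CCCCCGGGGG", pseudocount=0.04)
        (result,) = enrich(regions[:4], regions[4:], genome, [absent])
        assert result.p_value == 1.0

    def test_empty_background_rejected(self):
        genome, regions, motif = self.setup_population()
        with pytest.raises(ValueError):
            enrich(regions[:4], [], genome, [motif])

    def test_planted_motif_ranks_first(self, tiny_study):
        """The factor planted in most LMRs dominates the enrichment ranking."""
        genome = tiny_study.genome.sequences
        lmrs = tiny_study.genome.lmrs
        bg = build_background(lmrs, genome, n_per_fg=3, seed=1)
        results = enrich(lmrs, bg, genome, tiny_study.genome.motifs)
        assert results[0].motif == "Tfa"
        assert results[0].p_value < min(r.p_value for r in results[1:])

    def test_null_p_values_not_anticonservative(self):
        """Equal planting rates in fg and bg: rejections stay near or below alpha."""
        rng = np.random.default_rng(31)
        consensus = "TTGACGTCAA"
        motif = consensus_motif(consensus, pseudocount=0.04)
        n_sims, n_reject = 120, 0
        pvals = []
        for _ in range(n_sims):
            chunks, regions, cursor = [], [], 0
            for i in range(60):
                body = "".join(rng.choice(list("ACGT"), 60))
                if rng.random() < 0.3:
                    body = body[:20] + consensus + body[30:]
                chunks.append(body)
                regions.append(GenomicInterval("chr1", cursor, cursor + 60))
                cursor += 60
            genome = {"chr1": "".join(chunks)}
            (res,) = enrich(regions[:20], regions[20:], genome, [motif])
            pvals.append(res.p_value)
            n_reject += res.p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert n_reject / n_sims <= 0.05 + 3 * se
        assert np.median(pvals) > 0.2  # not degenerate


class TestBuildBackground:
    def test_lengths_match_and_disjoint_and_deterministic(self, tiny_study):
        genome = tiny_study.genome.sequences
        fg = tiny_study.genome.lmrs[:6]
        bg1 = build_background(fg, genome, n_per_fg=2, seed=9)
        bg2 = build_background(fg, genome, n_per_fg=2, seed=9)
        assert bg1 == bg2
        assert len(bg1) == 2 * len(fg)
        for i, b in enumerate(bg1):
            assert len(b) == len(fg[i // 2])
            assert not any(b.overlaps(f) for f in fg)

    def test_gc_matching_within_tolerance(self, tiny_study):
        genome = tiny_study.genome.sequences

        def gc(ivl):
            s = genome[ivl.chrom][ivl.start : ivl.end]
            return (s.count("G") + s.count("C")) / len(s)

        fg = tiny_study.genome.lmrs[:4]
        bg = build_background(fg, genome, n_per_fg=2, seed=2, gc_tol=0.05)
        for i, b in enumerate(bg):
            assert abs(gc(b) - gc(fg[i // 2])) <= 0.05 + 1e-9
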
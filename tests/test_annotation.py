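"""Overlap analysis, location classes, chain liftover, variant intersection."""

import numpy as np
import pandas as pd
import pytest

from methdyn.annotation import (
    Chain,
    ChainMap,
    GeneModel,
    annotate_regulatory,
    classify_location,
    gwas_ld_overlap,
    liftover,
    overlap,
)
from methdyn.io import GenomicInterval, MalformedInputError
from methdyn.targets import Interaction


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def bitmap_flags(query, track, min_bp):
    """Per-base bitmap oracle: flag if any single track element shares >= min_bp."""
    flags = []
    for q in query:
        hit = False
        for t in track:
            if t.chrom != q.chrom:
                continue
            shared = len(set(range(q.start, q.end)) & set(range(t.start, t.end)))
            if shared >= min_bp:
                hit = True
        flags.append(hit)
    return flags


class TestOverlap:
    def test_identical_sets_give_full_overlap(self):
        track = [iv(0, 10), iv(50, 80)]
        summary, flags = overlap(track, track)
        assert summary.percent == 100.0
        assert all(flags)

    def test_disjoint_sets_give_zero(self):
        summary, _ = overlap([iv(0, 10)], [iv(100, 120)])
        assert summary.percent == 0.0

    def test_min_bp_boundary(self):
        q, t = [iv(0, 10)], [iv(9, 20)]
        assert overlap(q, t, min_bp=1)[1] == [True]
        assert overlap(q, t, min_bp=2)[1] == [False]

    def test_empty_query_percent_missing(self):
        summary, _ = overlap([], [iv(0, 10)])
        assert summary.percent is None

    @pytest.mark.parametrize("min_bp", [1, 2, 10])
    def test_matches_bitmap_oracle(self, min_bp):
        rng = np.random.default_rng(17)
        def random_intervals(n):
            out = []
            for _ in range(n):
                start = int(rng.integers(0, 9_900))
                out.append(iv(start, start + int(rng.integers(1, 120))))
            return out

        query, track = random_intervals(60), random_intervals(40)
        _, flags = overlap(query, track, min_bp)
        assert flags == bitmap_flags(query, track, min_bp)


class TestAnnotateRegulatory:
    def test_three_way_classes(self):
        lmrs = [iv(0, 100), iv(200, 300), iv(400, 500)]
        dhs = [iv(0, 100), iv(200, 300)]
        ctcf = [iv(0, 100)]
        k4 = [iv(200, 300)]
        classes, summary = annotate_regulatory(
            lmrs, dhs, ctcf, k4, [True, False, False]
        )
        assert classes == ["CTCF-class", "enhancer-class", "non-DHS"]
        assert summary.percent == pytest.approx(100 * 2 / 3)
        assert summary.partition["CTCF-class"]["percent"] == pytest.approx(50.0)

    def test_motif_without_site_is_not_ctcf_class(self):
        classes, _ = annotate_regulatory(
            [iv(0, 100)], [iv(0, 100)], [], [iv(0, 100)], [True]
        )
        assert classes == ["enhancer-class"]


class TestClassifyLocation:
    GENES = [
        GeneModel("chr1", 10_000, 20_000, "+", "g1", ((10_000, 10_500), (15_000, 15_500))),
    ]

    def test_region_on_tss_is_promoter(self):
        out = classify_location([iv(9_900, 10_100)], self.GENES)
        row = out.iloc[0]
        assert row["location"] == "promoter"
        assert row["tss_distance"] == 0
        assert row["band"] == "promoter"

    def test_far_region_is_intergenic_distal(self):
        out = classify_location([iv(30_000, 30_400)], self.GENES)
        row = out.iloc[0]
        assert row["location"] == "intergenic"
        assert row["distal"]
        assert abs(row["tss_distance"]) > 5_000

    def test_intronic_distal(self):
        out = classify_location([iv(18_000, 18_300)], self.GENES)
        row = out.iloc[0]
        assert row["location"] == "intronic"
        assert row["distal"]

    def test_exonic(self):
        out = classify_location([iv(15_100, 15_200)], self.GENES)
        assert out.iloc[0]["location"] == "exonic"

    def test_partition_and_cgi_flag(self):
        regions = [iv(9_900, 10_100), iv(13_000, 13_200), iv(30_000, 30_100)]
        out = classify_location(regions, self.GENES, cgi_track=[iv(13_050, 13_500)])
        assert set(out["location"]) <= {"promoter", "exonic", "intronic", "intergenic"}
        assert out["location"].notna().all()
        assert out["cgi"].tolist() == [False, True, False]
        # 2-5 kb band is proximal, not promoter and not distal
        assert out.iloc[1]["band"] == "proximal"


def identity_chain(chrom="chr1", size=10_000):
    return Chain(
        score=100.0,
        t_name=chrom,
        t_size=size,
        t_start=0,
        t_end=size,
        q_name=chrom,
        q_size=size,
        q_strand="+",
        q_start=0,
        q_end=size,
        chain_id="1",
        blocks=[(0, size, 0)],
    )


def shift_chain(shift=100, chrom="chr1", size=10_000):
    return Chain(
        score=100.0,
        t_name=chrom,
        t_size=size,
        t_start=0,
        t_end=size,
        q_name=f"{chrom}_new",
        q_size=size + shift,
        q_strand="+",
        q_start=shift,
        q_end=size + shift,
        chain_id="2",
        blocks=[(0, size, shift)],
    )


class TestLiftover:
    def test_identity_chain_maps_to_self(self):
        result = liftover([iv(10, 20), iv(500, 900)], ChainMap([identity_chain()]))
        assert not result.unmapped
        for src, dst in result.mapped:
            assert (dst.chrom, dst.start, dst.end) == (src.chrom, src.start, src.end)

    def test_constant_shift(self):
        result = liftover([iv(10, 20)], ChainMap([shift_chain(100)]))
        ((_, dst),) = result.mapped
        assert (dst.chrom, dst.start, dst.end) == ("chr1_new", 110, 120)

    def test_half_covered_interval_is_partial(self):
        chain = identity_chain()
        chain.blocks = [(0, 50, 0)]  # only the first 50 bases align
        result = liftover([iv(0, 100)], ChainMap([chain]), min_match=0.95)
        ((_, reason),) = result.unmapped
        assert reason == "partial"

    def test_unknown_chrom_is_no_chain(self):
        result = liftover([iv(0, 10, chrom="chrX")], ChainMap([identity_chain()]))
        assert result.unmapped[0][1] == "no_chain"

    def test_split_across_chains(self):
        a = identity_chain()
        a.blocks = [(0, 50, 0)]
        b = identity_chain()
        b.chain_id = "9"
        b.blocks = [(50, 100, 50)]
        result = liftover([iv(0, 100)], ChainMap([a, b]), min_match=0.95)
        assert result.unmapped[0][1] == "split"

    def test_round_trip_through_inverse(self):
        chain_map = ChainMap([shift_chain(100)])
        inverse = chain_map.invert()
        src = [iv(10, 20), iv(123, 456)]
        fwd = liftover(src, chain_map)
        back = liftover([dst for _, dst in fwd.mapped], inverse)
        assert [(b.chrom, b.start, b.end) for _, b in back.mapped] == [
            (s.chrom, s.start, s.end) for s in src
        ]

    def test_chain_file_round_trip(self, tmp_path):
        cm = ChainMap([identity_chain(), shift_chain(100)])
        cm.to_file(tmp_path / "a.chain")
        back = ChainMap.from_file(tmp_path / "a.chain")
        assert len(back.chains) == 2
        assert back.chains[1].blocks == [(0, 10_000, 100)]
        result = liftover([iv(10, 20)], back)
        assert result.mapped[0][1].start == 10  # best chain is identity

    def test_malformed_chain_rejected(self, tmp_path):
        (tmp_path / "bad.chain").write_text("chain 100 chr1 1000\n")
        with pytest.raises(MalformedInputError):
            ChainMap.from_file(tmp_path / "bad.chain")


class TestGwasLdOverlap:
    INDEX = pd.DataFrame(
        [{"rsid": "rs1", "chrom": "chr1", "pos": 150, "trait": "hearing"}]
    )

    def ld(self, r2, distance=1000, pos=460):
        return pd.DataFrame(
            [
                {
                    "index_rsid": "rs1",
                    "proxy_rsid": "rs2",
                    "chrom": "chr1",
                    "pos": pos,
                    "r2": r2,
                    "distance": distance,
                }
            ]
        )

    LMRS = [iv(100, 200), iv(450, 550)]

    def test_low_r2_proxy_excluded(self):
        out = gwas_ld_overlap(self.INDEX, self.ld(0.4), self.LMRS)
        assert out["rsid"].tolist() == ["rs1"]

    def test_distant_proxy_excluded(self):
        out = gwas_ld_overlap(self.INDEX, self.ld(0.9, distance=600_000), self.LMRS)
        assert out["rsid"].tolist() == ["rs1"]

    def test_qualifying_proxy_and_gene_assignment(self):
        interactions = [Interaction(iv(120, 180), "Gjb6", "known")]
        out = gwas_ld_overlap(
            self.INDEX, self.ld(0.6), self.LMRS, interactions=interactions
        )
        assert set(out["rsid"]) == {"rs1", "rs2"}
        index_row = out[out["rsid"] == "rs1"].iloc[0]
        assert index_row["genes"] == "Gjb6"
        proxy_row = out[out["rsid"] == "rs2"].iloc[0]
        assert proxy_row["is_proxy"] and proxy_row["index_rsid"] == "rs1"
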
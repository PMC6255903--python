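"""Differential methylation: exact signed-rank test, windowing, calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methdyn.dmr import (
    DMRParams,
    call_dmrs,
    candidate_windows,
    rank_sum_test,
    signed_rank_test,
    test_window as window_test,
)

from conftest import brute_force_signed_rank, make_calls


class TestSignedRank:
    def test_six_concordant_pairs(self):
        """All six differences positive: p = 2 / 2^6 exactly."""
        delta, p = window_test([0.2] * 6, [0.6] * 6)
        assert p == pytest.approx(2 / 64)
        assert delta == pytest.approx(40.0)

    def test_five_concordant_pairs_miss_alpha(self):
        """With five pairs the exact two-sided floor is 2/32 > 0.05."""
        delta, p = window_test([0.2] * 5, [0.6] * 5)
        assert p == pytest.approx(2 / 32)
        assert p > 0.05

    def test_identical_levels(self):
        delta, p = window_test([0.3, 0.5, 0.7], [0.3, 0.5, 0.7])
        assert (delta, p) == (0.0, 1.0)

    @pytest.mark.parametrize("n", range(1, 13))
    def test_exact_matches_enumeration(self, n):
        """Exhaustive agreement with brute-force sign enumeration, n <= 12.

        Draws include heavy ties and zero differences, the cases where
        midranking and zero-dropping must match the oracle exactly.
        """
        rng = np.random.default_rng(100 + n)
        for _ in range(6):
            d = rng.choice([-0.4, -0.2, -0.1, 0.0, 0.1, 0.2, 0.4], size=n)
            assert signed_rank_test(d) == pytest.approx(
                brute_force_signed_rank(d), abs=1e-12
            )
        d = rng.normal(size=n)  # continuous, tie-free
        assert signed_rank_test(d) == pytest.approx(
            brute_force_signed_rank(d), abs=1e-12
        )

    def test_cross_check_against_scipy_exact(self):
        """Tie-free case: agrees with the reference exact implementation."""
        rng = np.random.default_rng(2)
        d = rng.normal(size=12)
        expected = stats.wilcoxon(d, alternative="two-sided", mode="exact").pvalue
        assert signed_rank_test(d) == pytest.approx(expected, abs=1e-12)

    def test_large_n_normal_approximation_is_close(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.2, 1.0, size=60)
        p = signed_rank_test(d)
        ref = stats.wilcoxon(d, alternative="two-sided", correction=True).pvalue
        assert p == pytest.approx(ref, rel=0.05)

    def test_rank_sum_variant(self):
        assert rank_sum_test([0.1, 0.2, 0.3], [0.7, 0.8, 0.9]) < 0.2

    @given(
        st.lists(
            st.sampled_from([-0.3, -0.15, -0.05, 0.0, 0.05, 0.15, 0.3]),
            min_size=1,
            max_size=10,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_p_property(self, d):
        """Any mixture of ties, zeros and signs agrees with enumeration."""
        assert signed_rank_test(d) == pytest.approx(
            brute_force_signed_rank(d), abs=1e-12
        )


class TestCandidateWindows:
    W10 = DMRParams(window=10, step=5)

    def test_exactly_one_window(self):
        a, b = make_calls([0.5] * 10), make_calls([0.5] * 10)
        assert len(candidate_windows(a, b, self.W10)) == 1

    def test_too_few_shared_cpgs(self):
        a, b = make_calls([0.5] * 4), make_calls([0.5] * 4)
        assert candidate_windows(a, b, self.W10) == []

    def test_fifteen_cpgs_two_windows(self):
        """15 shared CpGs at W=10, step 5: windows over CpGs 1-10 and 6-15."""
        a, b = make_calls([0.5] * 15), make_calls([0.5] * 15)
        windows = candidate_windows(a, b, self.W10)
        assert len(windows) == 2
        starts = [w.start for w in windows]
        pos = a["pos"].tolist()
        assert starts == [pos[0] - 1, pos[5] - 1]
        assert windows[1].end == pos[14]

    def test_max_span_excludes_sparse_windows(self):
        a = make_calls([0.5] * 10, spacing=700)  # full 10-CpG span 6.3 kb > 5 kb
        windows = candidate_windows(a, a, self.W10)
        # the oversized full window is dropped; only the in-span tail remains
        assert all(w.end - w.start <= 5000 for w in windows)
        assert len(windows) == 1 and len(windows[0]) <= 2900

    def test_only_shared_positions_are_windowed(self):
        a = make_calls([0.5] * 12)
        b = make_calls([0.5] * 12, start=1000 + 6 * 25)  # half-overlapping
        windows = candidate_windows(a, b, DMRParams(window=10, step=5, min_shared_cpg=5))
        assert len(windows) == 1  # 6 shared CpGs -> one short window


class TestCallDMRs:
    def planted_pair(self, delta=0.40, n=40, seed=0):
        rng = np.random.default_rng(seed)
        base = [0.85] * 60 + [0.85 - delta] * n + [0.85] * 60
        jitter = lambda lv: [  # noqa: E731
            min(1, max(0, x + rng.normal(0, 0.02))) for x in lv
        ]
        a = make_calls(jitter([0.85] * (120 + n)))
        b = make_calls(jitter(base))
        return a, b

    def test_planted_forty_pp_region_is_recovered(self):
        a, b = self.planted_pair()
        dmrs = call_dmrs(a, b, DMRParams(), transition="DevTrans")
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hypo"
        assert d.delta < -30
        assert d.transition == "DevTrans"
        # covers at least 80% of the planted span
        planted_start, planted_end = 1000 + 60 * 25, 1000 + 99 * 25
        covered = min(d.interval.end, planted_end) - max(d.interval.start, planted_start)
        assert covered / (planted_end - planted_start) >= 0.8

    def test_small_delta_never_called(self):
        a, b = self.planted_pair(delta=0.25)
        assert call_dmrs(a, b, DMRParams()) == []

    def test_swap_flips_directions(self):
        a, b = self.planted_pair()
        fwd = call_dmrs(a, b, DMRParams())
        rev = call_dmrs(b, a, DMRParams())
        assert len(fwd) == len(rev) == 1
        assert fwd[0].direction == "hypo" and rev[0].direction == "hyper"
        assert fwd[0].delta == pytest.approx(-rev[0].delta)
        assert fwd[0].p_value == pytest.approx(rev[0].p_value)

    def test_exact_thirty_pp_fails_strict_gate(self):
        """|delta| must exceed 30 points; equality is not enough."""
        a = make_calls([0.50] * 40, coverage=10)
        b = make_calls([0.20] * 40, coverage=10)
        assert call_dmrs(a, b, DMRParams()) == []
        _, flags = window_test([0.50] * 20, [0.20] * 20)
        # the window test itself is significant; only the gate excludes it
        assert flags < 0.05

    def test_every_call_passes_both_gates(self, tiny_study):
        from methdyn.io import merge_symmetric_cpg

        tps = tiny_study.spec.timepoints
        a = merge_symmetric_cpg(tiny_study.methylomes[tps[0]])
        b = merge_symmetric_cpg(tiny_study.methylomes[tps[1]])
        dmrs = call_dmrs(a, b, DMRParams(), transition="DevTrans")
        assert dmrs
        for d in dmrs:
            assert abs(d.delta) > 30
            assert d.q_value < 0.05
            assert d.q_value >= d.p_value
            assert (d.direction == "hyper") == (d.delta > 0)

    def test_recovers_planted_study_dmrs(self, tiny_study):
        from methdyn.evaluate import score_recovery
        from methdyn.io import merge_symmetric_cpg

        tps = tiny_study.spec.timepoints
        calls = {tp: merge_symmetric_cpg(tiny_study.methylomes[tp]) for tp in tps}
        recovered = 0
        planted_total = 0
        for tname, (ta, tb) in [
            ("DevTrans", (tps[0], tps[1])),
            ("MatTrans", (tps[1], tps[2])),
        ]:
            dmrs = call_dmrs(calls[ta], calls[tb], DMRParams(), transition=tname)
            planted = [
                d.interval
                for d in tiny_study.truth.planted_dmrs
                if d.transition == tname
            ]
            planted_total += len(planted)
            score = score_recovery([d.interval for d in dmrs], planted)
            recovered += round(score.recall * len(planted))
        assert planted_total > 0
        assert recovered / planted_total >= 0.9
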
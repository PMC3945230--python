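import math

import numpy as np
import pytest

from mosaicscan import (
    Genome,
    NullModel,
    RELAXED,
    call_traces,
    extract_flanks,
    permutation_window_tail,
    random_trace_probability,
    revcomp,
    trace_fraction,
)
from mosaicscan.mosaics import Mosaic
from mosaicscan.traces import SideCall, TraceCall, _call_side, FlankPair, global_align

from conftest import mutate_seq, random_seq
from oracles import binomial_tail


def _mosaic(g1_start, g1_end, g2_start, g2_end, strand="+"):
    return Mosaic(
        g1_id="a", g2_id="b", g1_start=g1_start, g1_end=g1_end,
        g2_start=g2_start, g2_end=g2_end, strand=strand,
        length=g1_end - g1_start, identity=0.97, score=100.0,
    )


def _trace_call(n: int) -> TraceCall:
    left = SideCall(side="left", testable=True, trace=n >= 1)
    right = SideCall(side="right", testable=True, trace=n >= 2)
    return TraceCall(mosaic=_mosaic(5000, 5400, 5000, 5400), left=left, right=right)


class TestExtractFlanks:
    def test_mid_genome_full_flanks(self):
        rng = np.random.default_rng(0)
        g1 = Genome("a", random_seq(rng, 30_000))
        g2 = Genome("b", random_seq(rng, 30_000))
        m = _mosaic(10_000, 10_400, 12_000, 12_400)
        left, right = extract_flanks(m, g1, g2)
        assert len(left.s1) == len(left.s2) == 2000
        assert len(right.s1) == len(right.s2) == 2000
        assert not left.truncated and not right.truncated
        # boundary-first: position 0 abuts the mosaic
        assert left.s1 == g1.seq[8000:10_000][::-1]
        assert right.s1 == g1.seq[10_400:12_400]
        assert left.s2 == g2.seq[10_000:12_000][::-1]
        assert right.s2 == g2.seq[12_400:14_400]

    def test_genome_start_truncates_left(self):
        rng = np.random.default_rng(1)
        g1 = Genome("a", random_seq(rng, 5000))
        g2 = Genome("b", random_seq(rng, 5000))
        m = _mosaic(0, 300, 0, 300)
        left, right = extract_flanks(m, g1, g2)
        assert left.truncated and len(left.s1) == 0
        assert not left.testable

    def test_minus_strand_slicing(self):
        rng = np.random.default_rng(2)
        g1 = Genome("a", random_seq(rng, 12_000))
        g2 = Genome("b", random_seq(rng, 12_000))
        m = _mosaic(5000, 5400, 6000, 6400, strand="-")
        left, right = extract_flanks(m, g1, g2, flank_len=1000)
        # left of the g1 segment continues past the g2 segment end on the
        # reverse-complement strand
        assert left.s2 == revcomp(g2.seq[6400:7400])[::-1]
        assert right.s2 == revcomp(g2.seq[5000:6000])
        assert left.s1 == g1.seq[4000:5000][::-1]


def _plant_pair(rng, b=0.60, anchor_left=True, anchor_right=False,
                anchor_identity=0.80, genome_len=12_000, mosaic_len=400):
    """One mosaic mid-genome with optional planted anchors."""
    s = random_seq(rng, genome_len)
    s2 = mutate_seq(rng, s, 1 - b)
    mid = genome_len // 2
    a, e = mid - mosaic_len // 2, mid + mosaic_len // 2
    s2 = s2[:a] + mutate_seq(rng, s[a:e], 0.03) + s2[e:]
    if anchor_left:
        s2 = s2[: a - 200] + mutate_seq(rng, s[a - 200 : a], 1 - anchor_identity) + s2[a:]
    if anchor_right:
        s2 = s2[:e] + mutate_seq(rng, s[e : e + 200], 1 - anchor_identity) + s2[e + 200 :]
    return Genome("a", s), Genome("b", s2), _mosaic(a, e, a, e)


class TestCallTraces:
    def test_left_anchor_only(self):
        rng = np.random.default_rng(3)
        g1, g2, m = _plant_pair(rng, anchor_left=True, anchor_right=False)
        call = call_traces(m, g1, g2, proximal_cols=250)
        assert call.left.trace
        assert call.n_traces >= 1

    def test_both_anchors_two_traces(self):
        rng = np.random.default_rng(4)
        g1, g2, m = _plant_pair(rng, anchor_left=True, anchor_right=True)
        call = call_traces(m, g1, g2, proximal_cols=250)
        assert call.left.trace and call.right.trace
        assert call.n_traces == 2

    def test_background_b_is_plausible(self):
        rng = np.random.default_rng(5)
        g1, g2, m = _plant_pair(rng)
        call = call_traces(m, g1, g2, proximal_cols=250)
        # forced global alignment inflates identity slightly above the
        # site-wise 0.60, but b must stay in a credible band
        for side in (call.left, call.right):
            assert 0.5 <= side.background_b <= 0.72

    def test_untestable_side_excluded(self):
        rng = np.random.default_rng(6)
        g1 = Genome("a", random_seq(rng, 3000))
        g2 = Genome("b", random_seq(rng, 3000))
        m = _mosaic(100, 400, 100, 400)
        call = call_traces(m, g1, g2)
        assert not call.left.testable
        assert call.untestable_sides >= 1

    def test_saturated_background_no_trace(self):
        rng = np.random.default_rng(7)
        s = random_seq(rng, 9000)
        s2 = mutate_seq(rng, s, 0.02)  # b ~ 0.98: no headroom for b + 0.10
        m = _mosaic(4300, 4700, 4300, 4700)
        call = call_traces(m, Genome("a", s), Genome("b", s2))
        assert call.n_traces == 0

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        g1, g2, m = _plant_pair(rng)
        c1 = call_traces(m, g1, g2, proximal_cols=500)
        c2 = call_traces(m, g1, g2, proximal_cols=500)
        assert c1.left == c2.left and c1.right == c2.right

    def test_anchor_free_rate_matches_null_on_positional_windows(self):
        # on the known site correspondence of an indel-free simulation,
        # window matches are exactly binomial: the observed per-side
        # trace rate must sit within 3 SE of the null-model expectation
        from mosaicscan import PairwiseAlignment, side_call_from_alignment

        rng = np.random.default_rng(9)
        n_sides = 100
        observed = expected = 0.0
        for _ in range(n_sides):
            s = random_seq(rng, 2000)
            s2 = mutate_seq(rng, s, 0.40)
            aln = PairwiseAlignment(
                g1_id="f1", g2_id="f2", g1_start=0, g1_end=2000,
                g2_start=0, g2_end=2000, strand="+", row1=s, row2=s2,
                score=0.0,
            )
            side = side_call_from_alignment(aln)
            observed += side.trace
            null = NullModel(b=side.background_b)
            expected += random_trace_probability(null, windows_per_side=40,
                                                 n_testable_sides=1)
        rate, exp_rate = observed / n_sides, expected / n_sides
        se = math.sqrt(max(exp_rate * (1 - exp_rate), 1e-6) / n_sides)
        assert abs(rate - exp_rate) <= 3 * se + 0.02

    def test_realigned_rate_bounded_by_binomial_null(self):
        # global realignment smooths window identities (gap slippage
        # lifts the low windows more than the high ones), so the
        # binomial null is a conservative upper bound for the
        # end-to-end anchor-free trace rate
        rng = np.random.default_rng(19)
        n_sides = 40
        observed = expected = 0.0
        for _ in range(n_sides):
            s = random_seq(rng, 2000)
            s2 = mutate_seq(rng, s, 0.40)
            side = _call_side(
                FlankPair(side="left", s1=s, s2=s2, truncated=False),
                RELAXED, 50, 0.10, 2000,
            )
            observed += side.trace
            null = NullModel(b=side.background_b)
            expected += random_trace_probability(null, windows_per_side=40,
                                                 n_testable_sides=1)
        rate, exp_rate = observed / n_sides, expected / n_sides
        se = math.sqrt(max(exp_rate * (1 - exp_rate), 1e-6) / n_sides)
        assert rate <= exp_rate + 3 * se + 0.02


class TestNullModel:
    def test_tail_matches_brute_force(self):
        null = NullModel(b=0.60, window_len=50, delta=0.10)
        k = math.ceil(50 * 0.70)
        assert null.q_window == pytest.approx(binomial_tail(50, 0.60, k), rel=1e-9)
        p = random_trace_probability(null, windows_per_side=1, n_testable_sides=1)
        assert p == pytest.approx(null.q_window, rel=1e-9)

    def test_saturated_threshold_probability_zero(self):
        null = NullModel(b=0.95, delta=0.10)
        assert random_trace_probability(null, 40, 100) == 0.0

    def test_multiple_windows_compound(self):
        null = NullModel(b=0.60)
        q = null.q_window
        p = random_trace_probability(null, windows_per_side=40, n_testable_sides=2)
        assert p == pytest.approx(1 - (1 - q) ** 80, rel=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            random_trace_probability(NullModel(b=0.6), 0, 1)

    def test_permutation_agrees_with_binomial(self):
        rng = np.random.default_rng(10)
        s = random_seq(rng, 2000)
        s2 = mutate_seq(rng, s, 0.40)
        aln = global_align(s, s2, RELAXED)
        emp = permutation_window_tail(aln, n_perm=300, seed=1)
        from mosaicscan import window_profile
        import statistics

        b_hat = statistics.median(window_profile(aln, 50).identities)
        q = NullModel(b=b_hat).q_window
        n = 300 * (len(aln) // 50)
        se = math.sqrt(q * (1 - q) / n)
        assert abs(emp - q) <= 3 * se + 0.01


class TestTraceFraction:
    def test_all_zero(self):
        calls = [_trace_call(0) for _ in range(5)]
        assert trace_fraction(calls) == 0.0

    def test_table_counts_give_32_percent(self):
        calls = (
            [_trace_call(0)] * 432 + [_trace_call(1)] * 169 + [_trace_call(2)] * 34
        )
        assert trace_fraction(calls) == pytest.approx(31.97, abs=0.05)

    def test_no_testable_is_nan(self):
        call = TraceCall(
            mosaic=_mosaic(0, 100, 0, 100),
            left=SideCall(side="left", testable=False),
            right=SideCall(side="right", testable=False),
        )
        assert math.isnan(trace_fraction([call]))


class TestMasking:
    def test_masked_side_loses_trace_other_unchanged(self):
        from mosaicscan import SimConfig, simulate_cohort

        base = dict(seed=23, n_pairs=4, genome_len=16_000, n_mosaics=2)
        cohorts = {}
        for p_mask in (0.0, 1.0):
            genomes, truth = simulate_cohort(SimConfig(p_mask=p_mask, **base))
            by_id = {g.id: g for g in genomes}
            calls = {}
            for pair in truth.pairs:
                for t in pair.mosaics:
                    m = _mosaic(t.start, t.end, t.start, t.end)
                    m.g1_id, m.g2_id = pair.g1_id, pair.g2_id
                    calls[(pair.g1_id, t.start)] = (
                        call_traces(m, by_id[pair.g1_id], by_id[pair.g2_id],
                                    proximal_cols=250),
                        t,
                    )
            cohorts[p_mask] = calls
        n_masked = 0
        for key, (call_masked, t_masked) in cohorts[1.0].items():
            call_clean, _ = cohorts[0.0][key]
            masked_sides = {a.side for a in t_masked.anchors if a.masked}
            if not masked_sides:
                continue
            n_masked += 1
            for side_name in ("left", "right"):
                clean = getattr(call_clean, side_name)
                masked = getattr(call_masked, side_name)
                if side_name in masked_sides:
                    assert clean.trace and not masked.trace
                else:
                    assert clean.trace == masked.trace
        assert n_masked >= 4
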
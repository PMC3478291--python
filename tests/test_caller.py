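"""Unit tests for the binning -> ratio -> smooth -> clr -> merge cascade."""

import numpy as np
import pytest
from scipy.stats import norm

from pairedcna import (
    AMPLIFICATION,
    DEFINED,
    DELETION,
    UDEF_AMPLIFICATION,
    UDEF_DELETION,
    UDEF_NEUTRAL,
    BinnedDepth,
    ClrWindow,
    DepthProfile,
    RatioBins,
    RunConfig,
    SimulatedEvent,
    bin_depths,
    call_scnas,
    clr_significance,
    clr_windows,
    match_events,
    merge_calls,
    pairwise_log_ratios,
    resolve_udef,
    simulate_depth_pair,
    simulate_events,
    smooth_ratios,
    summarize,
)


def profile(depths):
    return DepthProfile(chrom="chr1", depths=np.asarray(depths))


def binned(values, bin_size=50):
    return BinnedDepth(chrom="chr1", bin_size=bin_size, values=np.asarray(values, float))


class TestBinDepths:
    def test_constant_profile(self):
        out = bin_depths(profile([6] * 150), 50)
        assert list(out.values) == [6, 6, 6]

    def test_trailing_partial_bin_dropped(self):
        out = bin_depths(profile([1] * 120), 50)
        assert len(out) == 2

    def test_matches_bruteforce_windowed_average(self, rng):
        depths = rng.integers(0, 40, 1037)
        out = bin_depths(profile(depths), 50)
        brute = [depths[i * 50 : (i + 1) * 50].mean() for i in range(len(depths) // 50)]
        assert np.allclose(out.values, brute)

    def test_invalid_bin_size(self):
        with pytest.raises(ValueError):
            bin_depths(profile([1]), 0)


class TestPairwiseLogRatios:
    def test_power_of_two(self):
        out = pairwise_log_ratios(binned([8.0]), binned([4.0]), coverage_ratio=1)
        assert out.lr[0] == pytest.approx(1.0)
        assert out.tag[0] == DEFINED

    @pytest.mark.parametrize(
        "t,r,tag",
        [(0.0, 5.0, UDEF_DELETION), (5.0, 0.0, UDEF_AMPLIFICATION), (0.0, 0.0, UDEF_NEUTRAL)],
    )
    def test_udef_tagging(self, t, r, tag):
        out = pairwise_log_ratios(binned([t]), binned([r]), coverage_ratio=1)
        assert out.tag[0] == tag
        assert np.isnan(out.lr[0])

    def test_auto_coverage_ratio_centers_neutral_bins_at_zero(self):
        t, r = binned([8.0, 8.0, 8.0]), binned([4.0, 4.0, 4.0])
        out = pairwise_log_ratios(t, r, coverage_ratio="auto")
        assert np.allclose(out.lr, 0.0)

    def test_bin_count_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_log_ratios(binned([1.0]), binned([1.0, 2.0]))

    def test_auto_with_all_zero_ref(self):
        with pytest.raises(ValueError, match="auto"):
            pairwise_log_ratios(binned([1.0]), binned([0.0]), coverage_ratio="auto")


class TestResolveUdef:
    def test_inherits_neighboring_similar_event(self):
        bins = RatioBins(lr=[-1.2, np.nan], tag=[DEFINED, UDEF_DELETION])
        out = resolve_udef(bins, cap=5)
        assert out.lr[1] == pytest.approx(-1.2)
        assert out.tag[1] == UDEF_DELETION  # tag preserved

    def test_all_defined_is_noop(self):
        bins = RatioBins(lr=[0.5, -0.25, 0.0], tag=[DEFINED] * 3)
        out = resolve_udef(bins)
        assert np.allclose(out.lr, bins.lr)

    def test_isolated_amplification_gets_positive_cap(self):
        bins = RatioBins(lr=[np.nan], tag=[UDEF_AMPLIFICATION])
        out = resolve_udef(bins, cap=5)
        assert out.lr[0] == pytest.approx(5.0)

    def test_isolated_deletion_gets_negative_cap(self):
        bins = RatioBins(
            lr=[0.01, np.nan, 0.02], tag=[DEFINED, UDEF_DELETION, DEFINED]
        )
        out = resolve_udef(bins, cap=5)
        assert out.lr[1] == pytest.approx(-5.0)

    def test_neutral_gets_zero(self):
        bins = RatioBins(lr=[np.nan], tag=[UDEF_NEUTRAL])
        assert resolve_udef(bins).lr[0] == 0.0

    def test_near_zero_neighbor_below_floor_does_not_propagate(self):
        bins = RatioBins(lr=[-0.3, np.nan], tag=[DEFINED, UDEF_DELETION])
        out = resolve_udef(bins, cap=5, inherit_min=0.5)
        assert out.lr[1] == pytest.approx(-5.0)

    def test_run_inherits_from_nearest_matching_side(self):
        bins = RatioBins(
            lr=[-2.0, np.nan, np.nan, np.nan, -1.0],
            tag=[DEFINED, UDEF_DELETION, UDEF_DELETION, UDEF_DELETION, DEFINED],
        )
        out = resolve_udef(bins)
        assert list(out.lr) == pytest.approx([-2.0, -2.0, -2.0, -1.0, -1.0])

    def test_opposite_sign_neighbor_does_not_feed_udef(self):
        bins = RatioBins(lr=[1.5, np.nan], tag=[DEFINED, UDEF_DELETION])
        out = resolve_udef(bins, cap=5)
        assert out.lr[1] == pytest.approx(-5.0)


class TestSmoothing:
    def test_constant_series(self):
        assert np.allclose(smooth_ratios(np.full(12, 0.7), 4), 0.7)

    def test_hand_computed_forward_means_with_shrinking_tail(self):
        out = smooth_ratios(np.array([0, 0, 0, 0, 4, 4, 4, 4], float), 4)
        assert np.allclose(out, [0, 1, 2, 3, 4, 4, 4, 4])

    def test_matches_bruteforce_windowed_mean(self, rng):
        lr = rng.normal(size=57)
        out = smooth_ratios(lr, 4)
        brute = [lr[i : i + 4].mean() for i in range(len(lr))]
        assert np.allclose(out, brute)

    def test_empty_input(self):
        assert len(smooth_ratios(np.empty(0), 4)) == 0


class TestClrWindows:
    def test_constant_series_sums(self):
        w = clr_windows(np.full(19, 0.5), 10)
        assert len(w) == 10
        assert np.allclose(w.clr, 5.0)

    def test_all_zero(self):
        w = clr_windows(np.zeros(15), 10)
        assert np.allclose(w.clr, 0.0)
        assert np.allclose(w.p, 0.5)

    def test_matches_bruteforce_sliding_sums(self, rng):
        alr = rng.normal(size=43)
        w = clr_windows(alr, 10)
        brute = [alr[i : i + 10].sum() for i in range(34)]
        assert np.allclose(w.clr, brute, rtol=1e-12, atol=1e-12)

    def test_too_few_bins_gives_empty(self):
        assert len(clr_windows(np.zeros(5), 10)) == 0


class TestClrSignificance:
    def test_zero_clr_gives_half(self):
        z, p = clr_significance(0.0)
        assert z == 0.0
        assert p == pytest.approx(0.5)

    def test_threshold_clr_matches_normal_quantile(self):
        # the P=0.001 retention point is |clr| = isf(0.001)^2 * (n/4) with n=2
        z, p = clr_significance(norm.isf(0.001) ** 2 / 2.0)
        assert p == pytest.approx(0.001, rel=1e-6)
        _, p = clr_significance(4.775, n_samples=2)
        assert p == pytest.approx(0.001, rel=2e-3)

    def test_sign_is_ignored(self):
        assert clr_significance(-3.0) == clr_significance(3.0)

    def test_p_monotone_in_magnitude(self, rng):
        clrs = np.sort(np.abs(rng.normal(scale=5, size=50)))
        _, p = clr_significance(clrs)
        assert np.all(np.diff(p) <= 0)

    def test_nonfinite_clr_rejected(self):
        with pytest.raises(ValueError):
            clr_significance(np.nan)


def window(start, clr, k=10):
    z, p = clr_significance(clr)
    return ClrWindow(start_bin=start, k=k, clr=clr, z=z, p=p)


class TestMergeCalls:
    def test_no_significant_windows(self):
        assert merge_calls([window(0, 1.0)], 0.001, 50, 10) == []

    def test_isolated_window_yields_minimum_length_call(self):
        calls = merge_calls([window(7, 8.0)], 0.001, 50, 10, chrom="chr1")
        assert len(calls) == 1
        call = calls[0]
        assert (call.start, call.end) == (350, 850)
        assert call.length == 500
        assert call.kind == AMPLIFICATION

    def test_adjacent_opposite_signs_stay_separate(self):
        calls = merge_calls([window(0, -8.0), window(10, 8.0)], 0.001, 50, 10)
        assert len(calls) == 2
        assert [c.kind for c in calls] == [DELETION, AMPLIFICATION]

    def test_overlapping_same_sign_windows_fuse(self):
        calls = merge_calls([window(0, 8.0), window(4, 9.0), window(8, 8.5)], 0.001, 50, 10)
        assert len(calls) == 1
        assert calls[0].end - calls[0].start == 18 * 50
        assert calls[0].clr == 9.0  # most significant window's clr
        assert calls[0].p == min(window(0, 9.0).p, window(0, 8.0).p)

    def test_minimum_call_length_invariant(self, rng):
        wins = [window(int(s), float(c)) for s, c in
                zip(rng.integers(0, 200, 30), rng.normal(scale=8, size=30))]
        wins.sort(key=lambda w: w.start_bin)
        for call in merge_calls(wins, 0.001, 50, 10):
            assert call.length >= 500


class TestCallScnas:
    def test_identical_profiles_give_no_calls(self, rng):
        depths = rng.poisson(10, 100_000)
        p = profile(depths)
        assert call_scnas(p, profile(depths.copy())) == []

    def test_homozygous_deletion_recovered_within_margin(self):
        truth = [SimulatedEvent("chr1", 500_000, 505_000, DELETION, 0)]
        test, ref = simulate_depth_pair(1_000_000, truth, 30, seed=5)
        calls = call_scnas(test, ref)
        assert len(calls) == 1
        result = match_events(calls, truth, margin=0.10)
        assert len(result.matches) == 1
        assert calls[0].kind == DELETION

    def test_swapping_samples_exchanges_call_kinds(self):
        truth = [
            SimulatedEvent("chr1", 200_000, 230_000, DELETION, 1),
            SimulatedEvent("chr1", 600_000, 640_000, AMPLIFICATION, 4),
        ]
        test, ref = simulate_depth_pair(1_000_000, truth, 10, seed=9)
        config = RunConfig(coverage_ratio=1.0)
        fwd = call_scnas(test, ref, config)
        rev = call_scnas(ref, test, config)
        assert [(c.start, c.end) for c in fwd] == [(c.start, c.end) for c in rev]
        flip = {DELETION: AMPLIFICATION, AMPLIFICATION: DELETION}
        assert [flip[c.kind] for c in fwd] == [c.kind for c in rev]

    def test_chromosome_mismatch_rejected(self):
        a = DepthProfile("chr1", np.zeros(10, int))
        b = DepthProfile("chr2", np.zeros(10, int))
        with pytest.raises(ValueError, match="mismatch"):
            call_scnas(a, b)


def _sensitivity(coverage, seed):
    events = simulate_events(5_000_000, 0.015, (10_000, 50_000), seed=seed)
    test, ref = simulate_depth_pair(5_000_000, events, coverage, seed=seed + 1)
    calls = call_scnas(test, ref)
    return summarize(match_events(calls, events, margin=0.10)).sensitivity_pct


def test_sensitivity_saturates_at_moderate_coverage():
    """5X recovers 10-50 kb events essentially as well as 30X."""
    s5 = _sensitivity(5, seed=31)
    s30 = _sensitivity(30, seed=31)
    assert s5 >= 95.0
    assert s30 - s5 <= 5.0
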
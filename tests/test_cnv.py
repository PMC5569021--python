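"""Copy-number calling, consensus and profile comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chorline.cnv import (
    BALANCED,
    GAIN,
    LOSS,
    MISSING,
    CallThresholds,
    CnvProfile,
    CoverageTrack,
    GenomicInterval,
    acgh_log2,
    arm_summary,
    call_consensus,
    compare_profiles,
    compute_log2_profile,
)


def make_intervals(n, chrom="chr1", length=500, spacing=1000):
    return [GenomicInterval(chrom, i * spacing, i * spacing + length) for i in range(n)]


def profile_from_depths(depths, **kwargs):
    track = CoverageTrack("s", make_intervals(len(depths)), np.array(depths, float))
    return compute_log2_profile(track, **kwargs)


class TestLog2Profile:
    def test_uniform_coverage_is_balanced(self):
        prof = profile_from_depths([100.0] * 6)
        assert np.allclose(prof.log2_ratio, 0.0)
        assert all(c == BALANCED for c in prof.calls)

    def test_hand_computed_ratios_and_calls(self):
        prof = profile_from_depths([50, 100, 150, 100])
        assert np.allclose(prof.log2_ratio, [-1.0, 0.0, np.log2(1.5), 0.0])
        assert list(prof.calls) == [LOSS, BALANCED, GAIN, BALANCED]

    def test_cutoffs_are_strict_inequalities(self):
        th = CallThresholds()
        assert th.call(0.2) == BALANCED
        assert th.call(-0.2) == BALANCED
        assert th.call(np.nextafter(0.2, 1)) == GAIN
        assert th.call(np.nextafter(-0.2, -1)) == LOSS

    def test_zero_depth_gets_finite_floor_and_loss_call(self):
        prof = profile_from_depths([0, 100, 100, 100])
        assert prof.log2_ratio[0] == -8.0
        assert prof.calls[0] == LOSS

    def test_min_depth_marks_missing(self):
        prof = profile_from_depths([5, 100, 100, 100],
                                   thresholds=CallThresholds(min_depth=10))
        assert prof.calls[0] == MISSING and np.isnan(prof.log2_ratio[0])

    def test_all_zero_track_errors(self):
        with pytest.raises(ValueError, match="no coverage"):
            profile_from_depths([0.0, 0.0])

    def test_empty_track_errors(self):
        with pytest.raises(ValueError):
            compute_log2_profile(CoverageTrack("s", [], np.array([])))

    @given(st.lists(st.floats(min_value=1.0, max_value=1e4), min_size=2, max_size=30),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, depths, c):
        a = profile_from_depths(depths)
        b = profile_from_depths([d * c for d in depths])
        assert np.allclose(a.log2_ratio, b.log2_ratio, atol=1e-9)
        assert list(a.calls) == list(b.calls)

    @given(st.lists(st.floats(min_value=1.0, max_value=1e4), min_size=2, max_size=30))
    def test_raising_gain_cutoff_never_adds_gains(self, depths):
        lo = profile_from_depths(depths, thresholds=CallThresholds(gain_cutoff=0.2))
        hi = profile_from_depths(depths, thresholds=CallThresholds(gain_cutoff=0.5))
        assert (hi.calls == GAIN).sum() <= (lo.calls == GAIN).sum()

    def test_length_weighted_mean_option(self):
        ivs = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 1000)]
        track = CoverageTrack("s", ivs, np.array([100.0, 200.0]))
        prof = compute_log2_profile(track, length_weighted=True)
        weighted_mean = (100 * 100 + 200 * 800) / 900
        assert np.isclose(prof.log2_ratio[0], np.log2(100 / weighted_mean))


def _profile_with_calls(intervals, calls, sample="s"):
    ratio_for = {GAIN: 1.0, LOSS: -1.0, BALANCED: 0.0, MISSING: np.nan}
    return CnvProfile(sample, intervals,
                      np.array([ratio_for[c] for c in calls]),
                      np.array(calls, dtype=object))


class TestConsensus:
    def test_single_balanced_profile_is_zero_everywhere(self):
        ivs = make_intervals(4)
        cons = call_consensus([_profile_with_calls(ivs, [BALANCED] * 4)])
        assert np.all(cons.gain_pct == 0) and np.all(cons.loss_pct == 0)

    def test_three_of_four_gain_is_75_pct(self):
        ivs = make_intervals(1)
        profs = [_profile_with_calls(ivs, [GAIN], f"s{i}") for i in range(3)]
        profs.append(_profile_with_calls(ivs, [BALANCED], "s3"))
        assert call_consensus(profs).gain_pct[0] == 75.0

    def test_four_of_five_shared_gain_is_80_pct(self):
        # emulates the chr7 trisomy shared by all lines but one
        ivs = make_intervals(3, chrom="chr7")
        profs = [_profile_with_calls(ivs, [GAIN] * 3, f"line{i}") for i in range(4)]
        profs.append(_profile_with_calls(ivs, [BALANCED] * 3, "JHC7"))
        cons = call_consensus(profs)
        assert np.all(cons.gain_pct == 80.0)

    def test_missing_calls_excluded_from_both_sides(self):
        ivs = make_intervals(1)
        profs = [_profile_with_calls(ivs, [GAIN], "a"),
                 _profile_with_calls(ivs, [MISSING], "b")]
        assert call_consensus(profs).gain_pct[0] == 100.0

    def test_mismatched_interval_lists_error(self):
        with pytest.raises(ValueError, match="mismatched"):
            call_consensus([
                _profile_with_calls(make_intervals(2), [GAIN] * 2, "a"),
                _profile_with_calls(make_intervals(3), [GAIN] * 3, "b"),
            ])

    def test_matches_bruteforce_tally_on_random_profiles(self, rng):
        ivs = make_intervals(20)
        states = np.array([GAIN, LOSS, BALANCED, MISSING], dtype=object)
        for _ in range(25):
            profs = [_profile_with_calls(ivs, list(rng.choice(states, 20)), f"s{i}")
                     for i in range(rng.integers(1, 7))]
            cons = call_consensus(profs)
            for i in range(20):
                col = [p.calls[i] for p in profs if p.calls[i] != MISSING]
                exp_gain = 100 * col.count(GAIN) / len(col) if col else 0.0
                exp_loss = 100 * col.count(LOSS) / len(col) if col else 0.0
                assert cons.gain_pct[i] == pytest.approx(exp_gain)
                assert cons.loss_pct[i] == pytest.approx(exp_loss)


class TestAcgh:
    def test_equal_channels_balanced(self):
        ivs = make_intervals(3)
        prof = acgh_log2(ivs, np.ones(3), np.ones(3))
        assert np.allclose(prof.log2_ratio, 0) and all(c == BALANCED for c in prof.calls)

    def test_1p5_fold_is_gain(self):
        ivs = make_intervals(1)
        prof = acgh_log2(ivs, np.array([1.5]), np.array([1.0]))
        assert prof.log2_ratio[0] == pytest.approx(np.log2(1.5))
        assert prof.calls[0] == GAIN

    def test_zero_reference_channel_is_missing_not_error(self):
        ivs = make_intervals(2)
        prof = acgh_log2(ivs, np.array([1.0, 1.0]), np.array([0.0, 1.0]))
        assert prof.calls[0] == MISSING and prof.calls[1] == BALANCED

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            acgh_log2(make_intervals(2), np.ones(2), np.ones(3))

    def test_ratio_exactly_at_cutoff_is_balanced(self):
        # log2(4/1) = 2.0 exactly; with gain_cutoff = 2.0 the strict
        # inequality leaves the probe balanced
        prof = acgh_log2(make_intervals(1), np.array([4.0]), np.array([1.0]),
                         thresholds=CallThresholds(gain_cutoff=2.0))
        assert prof.log2_ratio[0] == 2.0
        assert prof.calls[0] == BALANCED


class TestCompareProfiles:
    def test_self_comparison_is_unity(self):
        prof = profile_from_depths([50, 100, 150, 100])
        assert compare_profiles(prof, prof).concordance == 1.0

    def test_two_of_ten_discordant_is_0p8(self):
        ivs = make_intervals(10)
        a = _profile_with_calls(ivs, [BALANCED] * 10, "a")
        b = _profile_with_calls(ivs, [GAIN, LOSS] + [BALANCED] * 8, "b")
        rep = compare_profiles(a, b)
        assert rep.concordance == pytest.approx(0.8)
        assert rep.confusion[(BALANCED, GAIN)] == 1
        assert rep.confusion[(BALANCED, LOSS)] == 1

    def test_symmetric(self):
        ivs = make_intervals(6)
        a = _profile_with_calls(ivs, [GAIN, LOSS, BALANCED, GAIN, MISSING, LOSS], "a")
        b = _profile_with_calls(ivs, [LOSS, LOSS, GAIN, GAIN, BALANCED, MISSING], "b")
        assert (compare_profiles(a, b).concordance
                == compare_profiles(b, a).concordance)

    def test_empty_intersection_errors(self):
        a = _profile_with_calls(make_intervals(2, chrom="chr1"), [GAIN] * 2, "a")
        b = _profile_with_calls(make_intervals(2, chrom="chr2"), [GAIN] * 2, "b")
        with pytest.raises(ValueError, match="share no intervals"):
            compare_profiles(a, b)


def test_arm_summary_flags_q_arm_loss():
    # intervals on chr2q called loss, chr2p balanced
    ivs = [GenomicInterval("chr2", 10_000_000, 10_000_500),
           GenomicInterval("chr2", 100_000_000, 100_000_500),
           GenomicInterval("chr2", 200_000_000, 200_000_500)]
    prof = _profile_with_calls(ivs, [BALANCED, LOSS, LOSS])
    rows = {(r["chrom"], r["arm"]): r for r in arm_summary(prof)}
    assert rows[("chr2", "q")]["state"] == LOSS
    assert rows[("chr2", "p")]["state"] == BALANCED
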
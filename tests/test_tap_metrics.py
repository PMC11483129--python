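import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from ufiberlab.tap_metrics import (absolute_asynchrony, constant_error,
                                   lag1_autocorrelation, pair_taps,
                                   summarize_subject, temporal_variability,
                                   validate_trial)
from ufiberlab.tapping_sim import TappingSession, Trial


class TestPairing:
    def test_basic_asynchronies(self):
        pairs, _, _ = pair_taps([0, 750, 1500], [-50, 700, 1480], 750)
        asyn = [t - s for s, t in pairs]
        assert asyn == [-50, -50, -20]

    def test_half_target_tie_goes_to_earlier_stimulus(self):
        # tap at 375 is exactly halfway between stimuli 0 and 750
        pairs, un_stim, _ = pair_taps([0.0, 750.0], [375.0], 750.0)
        assert pairs == [(0.0, 375.0)]
        assert un_stim == [750.0]

    def test_closest_tap_wins_single_assignment(self):
        pairs, _, un_taps = pair_taps([0.0], [-30.0, 10.0], 750.0)
        assert pairs == [(0.0, 10.0)]
        assert un_taps == [-30.0]

    def test_matches_optimal_assignment_on_jittered_streams(self):
        rng = np.random.default_rng(0)
        target = 750.0
        for _ in range(30):
            stim = np.arange(10) * target
            taps = np.sort(stim + rng.normal(-40, 60, 10))
            pairs, _, _ = pair_taps(stim, taps, target)
            # oracle: min-cost one-to-one assignment within half a target
            cost = np.abs(stim[:, None] - taps[None, :])
            big = 1e9
            cost = np.where(cost <= target / 2, cost, big)
            ri, ci = linear_sum_assignment(cost)
            oracle = {(stim[i], taps[j]) for i, j in zip(ri, ci)
                      if cost[i, j] < big}
            assert set(pairs) == oracle


class TestMetricArithmetic:
    def test_absolute_asynchrony(self):
        pairs = [(0, -50), (750, 700), (1500, 1480)]
        assert absolute_asynchrony(pairs) == pytest.approx(40.0)
        assert absolute_asynchrony([(0, 0), (750, 750)]) == 0.0
        assert np.isnan(absolute_asynchrony([]))

    def test_constant_error(self):
        assert constant_error([780, 780, 780], 750) == pytest.approx(30.0)
        assert constant_error([750.0] * 6, 750) == 0.0
        assert np.isnan(constant_error([], 750))

    def test_temporal_variability(self):
        assert temporal_variability([750.0] * 6) == 0.0
        assert temporal_variability([700.0, 800.0]) == pytest.approx(
            70.7107, abs=1e-3)  # n-1 denominator
        assert np.isnan(temporal_variability([]))

    def test_lag1_hand_computed(self):
        r = lag1_autocorrelation([[600, 700, 600, 700, 600, 700]])
        assert r == pytest.approx(-12500.0 / 15000.0, abs=1e-12)

    def test_lag1_trend_positive(self):
        assert lag1_autocorrelation([[1, 2, 3, 4, 5, 6]]) > 0

    def test_lag1_zero_variance_trial_skipped(self):
        r = lag1_autocorrelation([[750.0] * 6, [600, 700, 600, 700, 600, 700]])
        assert r == pytest.approx(-12500.0 / 15000.0)

    def test_lag1_short_series_rejected(self):
        with pytest.raises(ValueError):
            lag1_autocorrelation([[1.0, 2.0]])


def _trial_with_intervals(sync_iv, cont_iv, target=750.0):
    taps_sync = np.concatenate([[0.0], np.cumsum(sync_iv)])
    taps = np.concatenate([taps_sync, taps_sync[-1] + np.cumsum(cont_iv)])
    stim = np.arange(len(sync_iv) + 1) * target
    return Trial("auditory", target, stim, taps, n_sync=len(sync_iv))


class TestValidity:
    def test_sync_threshold_worked_example(self):
        iv = [700, 800, 760, 740, 755, 976]  # 976 deviates 226 > 0.3*750
        t = _trial_with_intervals(iv, [750.0] * 6)
        sync_ok, cont_ok = validate_trial(t)
        assert not sync_ok
        assert cont_ok

    def test_cont_threshold_worked_example(self):
        iv = [700, 800, 760, 740, 755, 976]  # 226 < 0.4*750 = 300
        t = _trial_with_intervals([750.0] * 6, iv)
        sync_ok, cont_ok = validate_trial(t)
        assert sync_ok
        assert cont_ok

    def test_perfect_trial_valid_in_both(self):
        t = _trial_with_intervals([750.0] * 6, [750.0] * 6)
        assert validate_trial(t) == (True, True)


class TestSummaries:
    def test_perfect_session_all_zero(self):
        trials = [_trial_with_intervals([750.0] * 6, [750.0] * 6)
                  for _ in range(3)]
        s = summarize_subject(TappingSession(0, trials))
        cell = s.cells[("auditory", 750.0)]
        assert cell["mean_abs_asynchrony"] == 0.0
        assert cell["constant_error_sync"] == 0.0
        assert cell["constant_error_cont"] == 0.0
        assert cell["temporal_variability_sync"] == 0.0
        assert cell["n_valid_trials"] == 3

    def test_hand_built_two_trial_session(self):
        t1 = _trial_with_intervals([740.0] * 6, [760.0] * 6)
        t2 = _trial_with_intervals([760.0] * 6, [740.0] * 6)
        s = summarize_subject(TappingSession(0, [t1, t2]))
        cell = s.cells[("auditory", 750.0)]
        assert cell["constant_error_sync"] == pytest.approx(0.0)
        assert cell["constant_error_cont"] == pytest.approx(0.0)
        # 6 intervals at 740 and 6 at 760: SD = 10 * sqrt(12/11)
        assert cell["temporal_variability_sync"] == pytest.approx(
            10 * np.sqrt(12 / 11.0))

    def test_invalid_trials_excluded(self):
        good = _trial_with_intervals([750.0] * 6, [750.0] * 6)
        bad = _trial_with_intervals([750.0] * 5 + [1200.0], [750.0] * 6)
        s = summarize_subject(TappingSession(0, [good, bad]))
        assert s.cells[("auditory", 750.0)]["n_valid_trials"] == 1

    def test_no_valid_trials_warns_missing(self):
        bad = _trial_with_intervals([1200.0] * 6, [750.0] * 6)
        with pytest.warns(UserWarning, match="no valid trials"):
            s = summarize_subject(TappingSession(0, [bad]))
        assert np.isnan(s.cells[("auditory", 750.0)]["mean_abs_asynchrony"])


@given(shift=st.floats(-1e5, 1e5, allow_nan=False))
@settings(max_examples=25, deadline=None)
def test_metrics_invariant_to_global_time_shift(shift):
    iv_s = [740.0, 755.0, 760.0, 745.0, 752.0, 748.0]
    iv_c = [730.0, 770.0, 750.0, 740.0, 765.0, 745.0]
    t0 = _trial_with_intervals(iv_s, iv_c)
    t1 = Trial(t0.modality, t0.target_ms, t0.stimulus_onsets + shift,
               t0.tap_onsets + shift, t0.n_sync)
    s0 = summarize_subject(TappingSession(0, [t0]))
    s1 = summarize_subject(TappingSession(0, [t1]))
    c0 = s0.cells[("auditory", 750.0)]
    c1 = s1.cells[("auditory", 750.0)]
    for k in c0:
        assert c1[k] == pytest.approx(c0[k], abs=1e-6)


@given(st.lists(st.floats(-100, 100), min_size=3, max_size=8))
@settings(max_examples=50, deadline=None)
def test_abs_asynchrony_bounds_signed_mean(asyncs):
    pairs = [(i * 750.0, i * 750.0 + a) for i, a in enumerate(asyncs)]
    assert absolute_asynchrony(pairs) >= abs(np.mean(asyncs)) - 1e-9


@given(st.lists(st.floats(100, 1000), min_size=3, max_size=10))
@settings(max_examples=50, deadline=None)
def test_lag1_in_unit_interval(series):
    r = lag1_autocorrelation([series])
    if not np.isnan(r):
        assert -1.0 - 1e-9 <= r <= 1.0 + 1e-9
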
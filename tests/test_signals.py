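"""Conditioning and segmentation: zero-phase filtering, contact events,
stride extraction and the sit/stand phase equations."""

import numpy as np
import pandas as pd
import pytest

from kneeload.signals import (
    EventNotFoundError,
    detect_heel_strikes,
    detect_sit_to_stand,
    detect_stand_to_sit,
    extract_strides,
    filter_dual_pass,
)
from kneeload.synthetic import GaitTrialSpec, StsTrialSpec, generate_gait_trial, generate_sts_trace
from kneeload.trial import CHANNELS, FilterSpec, PhaseWindow, TrialTimeSeries


def _sine(freq_hz, rate_hz=1000.0, duration_s=4.0):
    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    return t, np.sin(2 * np.pi * freq_hz * t)


class TestDualPassFilter:
    def test_dc_gain_is_unity(self):
        out = filter_dual_pass(np.full(2000, 5.0), FilterSpec(45.0), 1000.0)
        assert np.allclose(out, 5.0)

    @pytest.mark.parametrize(
        "freq, lo, hi",
        [
            (45.0, 0.48, 0.52),  # squared -3 dB point: two passes halve the amplitude
            (1.0, 0.999, 1.001),  # deep passband
        ],
    )
    def test_magnitude_response_at_45hz_cutoff(self, freq, lo, hi):
        t, x = _sine(freq)
        y = filter_dual_pass(x, FilterSpec(45.0), 1000.0)
        core = slice(1000, 3000)  # avoid edge transients
        ratio = y[core].std() / x[core].std()
        assert lo <= ratio <= hi

    def test_zero_phase(self):
        freq = 10.0
        t, x = _sine(freq)
        y = filter_dual_pass(x, FilterSpec(45.0), 1000.0)
        core = slice(1000, 3000)
        # project the output on the quadrature pair: zero lag means no
        # cosine leakage
        phase = np.arctan2(
            np.dot(y[core], np.cos(2 * np.pi * freq * t[core])),
            np.dot(y[core], np.sin(2 * np.pi * freq * t[core])),
        )
        assert abs(phase) < 1e-3

    def test_preserves_length(self):
        x = np.random.default_rng(0).normal(size=777)
        assert len(filter_dual_pass(x, FilterSpec(6.0), 200.0)) == 777

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            filter_dual_pass(np.zeros(1000), FilterSpec(500.0), 1000.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            filter_dual_pass(np.zeros(10), FilterSpec(45.0), 1000.0)


class TestHeelStrikes:
    def test_single_step_crossing(self):
        fz = np.zeros(3000)
        fz[1200:] = 500.0
        events = detect_heel_strikes(fz, 1000.0)
        assert len(events) == 1
        assert abs(events[0] - 1200) <= 1

    def test_no_contact_gives_empty(self):
        assert len(detect_heel_strikes(np.zeros(2000), 1000.0)) == 0

    def test_brief_spike_rejected_by_sustain(self):
        fz = np.zeros(3000)
        fz[1000:1004] = 300.0  # 4 ms blip
        fz[2000:] = 600.0
        events = detect_heel_strikes(fz, 1000.0)
        assert list(events) == [2000]

    def test_synthetic_run_trial_strike_count_and_cadence(self):
        spec = GaitTrialSpec(movement_class="run_selfselect", n_strides=5, seed=3)
        trial, truth = generate_gait_trial(spec)
        events = detect_heel_strikes(trial["fz"], trial.rate_hz)
        assert len(events) == 6
        gaps = np.diff(events) / trial.rate_hz
        assert np.all(np.abs(gaps - spec.stride_duration_s) < 0.05 * spec.stride_duration_s)


def _trial_of_length(n, rate=1000.0):
    df = pd.DataFrame({c: np.zeros(n) for c in CHANNELS})
    df["time"] = np.arange(n) / rate
    return TrialTimeSeries(df, rate)


class TestStrides:
    def test_three_events_two_windows(self):
        trial = _trial_of_length(4000)
        windows = extract_strides(np.array([100, 1200, 2300]), trial)
        assert [(w.start_index, w.end_index) for w in windows] == [(100, 1200), (1200, 2300)]

    def test_outlier_duration_removed_then_capped_at_five(self):
        # six strides, one with a wildly long duration; rule keeps five
        events = np.array([0, 1000, 2000, 3000, 5500, 6500, 7500])
        trial = _trial_of_length(8000)
        windows = extract_strides(events, trial)
        assert len(windows) == 5
        assert (3000, 5500) not in [(w.start_index, w.end_index) for w in windows]

    def test_single_event_is_error(self):
        with pytest.raises(EventNotFoundError, match="no stride"):
            extract_strides(np.array([100]), _trial_of_length(1000))

    def test_windows_ordered_and_non_overlapping(self):
        trial = _trial_of_length(6000)
        windows = extract_strides(np.array([0, 1100, 2200, 3300, 4400, 5500]), trial)
        for w1, w2 in zip(windows, windows[1:]):
            assert w1.end_index <= w2.start_index
            assert w1.start_index < w1.end_index


class TestSitStandPhases:
    def test_noise_free_boundary_recovery(self, clean_sts):
        (trial, truth), _ = clean_sts
        sts = detect_sit_to_stand(trial, truth.bodyweight_n)
        s2s = detect_stand_to_sit(trial, truth.bodyweight_n)
        assert abs(sts.start_index - truth.events["sit_to_stand"][0]) <= 5
        assert abs(s2s.start_index - truth.events["stand_to_sit"][0]) <= 5
        assert sts.start_index < sts.end_index
        assert s2s.start_index < s2s.end_index
        assert sts.end_index <= s2s.start_index  # phases do not overlap

    def test_quiet_standing_mean_force_matches_bodyweight(self):
        spec = StsTrialSpec(bodyweight_n=700.0, seed=2)
        trial, truth = generate_sts_trace(spec)
        b2, b3 = spec.phase_boundaries[2], spec.phase_boundaries[3]
        mean_fz = trial["fz"][b2:b3].mean()
        assert 693.0 <= mean_fz <= 707.0

    def test_doubled_bodyweight_gives_no_event(self, clean_sts):
        (trial, truth), _ = clean_sts
        with pytest.raises(EventNotFoundError, match="no event"):
            detect_stand_to_sit(trial, 2 * truth.bodyweight_n)

    def test_all_quiet_trace_gives_no_event(self):
        n = 5000
        df = pd.DataFrame({c: np.zeros(n) for c in CHANNELS})
        df["time"] = np.arange(n) / 1000.0
        df["fz"] = 700.0
        trial = TrialTimeSeries(df, 1000.0)
        with pytest.raises(EventNotFoundError, match="no event"):
            detect_sit_to_stand(trial, 700.0)

    def test_zero_pelvis_velocity_clause_dominates_end(self, clean_sts):
        (trial, truth), _ = clean_sts
        quiet = trial.copy_with(pelvis_vz=np.zeros(len(trial)))
        window = detect_stand_to_sit(quiet, truth.bodyweight_n)
        # velocity clause holds everywhere: end fires at the first post-start sample
        assert window.end_index == window.start_index + 1

    def test_step_directly_to_bodyweight(self):
        n, k, bw = 6000, 3000, 700.0
        df = pd.DataFrame({c: np.zeros(n) for c in CHANNELS})
        df["time"] = np.arange(n) / 1000.0
        fz = np.full(n, 0.3 * bw)
        fz[k:] = bw
        df["fz"] = fz
        trial = TrialTimeSeries(df, 1000.0)
        window = detect_sit_to_stand(trial, bw)
        # smoothing spreads the step symmetrically; the standing band is
        # entered within the filter settling time of the step sample
        assert k - 400 <= window.start_index < window.end_index <= k + 400

    def test_never_reaching_standing_band_gives_no_event(self):
        spec = StsTrialSpec(seed=4)
        trial, truth = generate_sts_trace(spec)
        with pytest.raises(EventNotFoundError, match="no event"):
            detect_sit_to_stand(trial, 1.5 * truth.bodyweight_n)


class TestBoundaryRecoveryUnderNoise:
    def test_recovery_rate_at_two_percent_bodyweight_noise(self):
        """>= 95% of planted phase boundaries recovered within +/- 20 ms
        over 100 seeded trials at 2% BW force noise."""
        hits = total = 0
        tol = 20  # samples at 1 kHz == 20 ms
        for seed in range(100):
            spec = StsTrialSpec(noise_sd=0.02 * 700.0, noise_sd_vz=0.005, seed=seed)
            trial, truth = generate_sts_trace(spec)
            sts = detect_sit_to_stand(trial, truth.bodyweight_n)
            s2s = detect_stand_to_sit(trial, truth.bodyweight_n)
            detected = [sts.start_index, sts.end_index, s2s.start_index, s2s.end_index]
            planted = [*truth.events["sit_to_stand"], *truth.events["stand_to_sit"]]
            for d, p in zip(detected, planted):
                hits += abs(d - p) <= tol
                total += 1
        assert total == 400
        assert hits / total >= 0.95


def test_phase_window_validation():
    with pytest.raises(ValueError):
        PhaseWindow("stance", 10, 10)
    with pytest.raises(ValueError):
        PhaseWindow("stance", -1, 5)
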
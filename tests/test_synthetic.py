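import numpy as np
import pytest

from arrayqc import compute_muae
from arrayqc.errors import ConfigurationError
from arrayqc.evoked import extract_trials
from arrayqc.synthetic import (DIRECTION_CODES, SessionSpec, SynchrofactGroup,
                               channel_trace, default_rf_centres,
                               generate_bar_trials, generate_crossing_raster,
                               generate_event_stream, generate_eye_signals,
                               generate_ground_truth, generate_session)


def _spec(**kw):
    base = dict(task_kind="resting", duration=10.0, n_arrays=2,
                electrodes_per_array=2, seed=5)
    base.update(kw)
    return SessionSpec(**base)


class TestDeterminism:
    def test_same_seed_identical_bytes(self):
        spec = _spec(duration=5.0, synchrofact_groups=(
            SynchrofactGroup(members=(1, 2), rate_hz=2.0),))
        s1, g1 = generate_session(spec)
        s2, g2 = generate_session(spec)
        for f1, f2 in zip(s1.files, s2.files):
            np.testing.assert_array_equal(f1.signals, f2.signals)
            np.testing.assert_array_equal(f1.events.samples, f2.events.samples)
        np.testing.assert_array_equal(g1.nsp_offsets, g2.nsp_offsets)

    def test_different_seed_differs(self):
        s1, _ = generate_session(_spec(duration=2.0, seed=1))
        s2, _ = generate_session(_spec(duration=2.0, seed=2))
        assert not np.array_equal(s1.files[0].signals, s2.files[0].signals)

    def test_noiseless_trials_identical(self):
        """With noise_sd = 0 the evoked signal is fully deterministic, so
        per-trial traces repeat exactly."""
        spec = _spec(task_kind="snr", duration=14.0, noise_sd=0.0,
                     evoked_amplitude=1.0, nsp_offsets=np.zeros((1, 2), int))
        gt = generate_ground_truth(spec)
        mu = compute_muae(channel_trace(spec, gt, 1)).data
        onset_bins = (gt.trials.onset_sample.to_numpy() // 30).astype(int)
        trials = extract_trials(mu, onset_bins, 300, 400)
        assert trials.shape[0] >= 5
        np.testing.assert_allclose(trials, np.tile(trials[0], (trials.shape[0], 1)),
                                   atol=1e-9)


class TestEventStream:
    def test_resting_sync_codes(self):
        ev = generate_event_stream(_spec(duration=60.0))
        assert len(ev) == 60
        assert ev.codes.min() >= 1 and ev.codes.max() <= 8
        # 1-second spacing
        np.testing.assert_array_equal(np.diff(ev.samples), 30_000)

    def test_snr_task_codes(self):
        spec = _spec(task_kind="snr", duration=14.0, per_channel_snr=3.0)
        ev = generate_event_stream(spec)
        n_trials = int(14.0 // spec.snr_trial_period)
        # onset (2), offset (4), reward (8) per trial
        assert (ev.codes == 2).sum() == n_trials
        assert (ev.codes == 4).sum() == n_trials
        assert (ev.codes == 8).sum() == n_trials
        onsets = ev.samples[ev.codes == 2]
        offsets = ev.samples[ev.codes == 4]
        # onset 400 ms after trial start, offset 400 ms later
        np.testing.assert_array_equal(onsets % int(spec.snr_trial_period * 30_000),
                                      int(0.4 * 30_000))
        np.testing.assert_array_equal(offsets - onsets, 12_000)

    def test_rf_direction_codes(self):
        n_ch = 4
        spec = _spec(task_kind="rf", duration=32.0, per_channel_snr=3.0,
                     rf_centres=default_rf_centres(n_ch, 1))
        ev = generate_event_stream(spec)
        cond = ev.codes[np.isin(ev.codes, list(DIRECTION_CODES.values()))]
        assert set(cond) == {8, 16, 32, 64}
        assert (ev.codes == 2).sum() == cond.size  # one onset per condition

    def test_single_active_bit_encoding(self):
        # decimal code for active bit N is 2**N
        assert DIRECTION_CODES["rightward"] == 2 ** 3
        assert DIRECTION_CODES["downward"] == 2 ** 6


class TestEyeSignals:
    def test_baseline_offset_and_floor(self):
        spec = _spec(duration=20.0, closure_schedule=((5.0, 9.0),),
                     blink_rate_hz=0.0)
        eye, blinks = generate_eye_signals(spec)
        bx, by = spec.pupil_baseline
        # during closure the diameter sits at its baseline offset
        assert abs(eye.pupil_x.min() - bx) < 0.05
        assert abs(eye.pupil_y.min() - by) < 0.05
        assert blinks.shape == (0, 2)

    def test_no_closures_never_near_floor(self):
        spec = _spec(duration=10.0, blink_rate_hz=0.0)
        eye, _ = generate_eye_signals(spec)
        bx, _ = spec.pupil_baseline
        # stays well above baseline: no sub-threshold samples to misread
        assert eye.pupil_x.min() > bx + 0.5 * spec.pupil_scale

    def test_overlapping_closures_rejected(self):
        with pytest.raises(ConfigurationError):
            _spec(closure_schedule=((1.0, 5.0), (4.0, 6.0))).validate()

    def test_closure_outside_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            _spec(closure_schedule=((5.0, 20.0),)).validate()


class TestBarTrials:
    def test_geometry_and_peak_timing(self):
        """The planted response envelope peaks when the bar reaches the RF
        centre: (centre - start) / speed seconds after sweep onset."""
        centres = np.tile([[1.5, -1.5]], (4, 1))
        spec = _spec(task_kind="rf", duration=16.0, rf_centres=centres,
                     per_channel_snr=5.0, per_channel_latency_ms=0.0)
        gt = generate_ground_truth(spec)
        trials = gt.trials
        assert set(trials.direction[:4]) == {"rightward", "upward",
                                             "leftward", "downward"}
        from arrayqc.synthetic import evoked_envelope
        env = evoked_envelope(spec, gt, 1)
        t0 = trials.iloc[0]  # rightward
        expect = t0.onset_sample / 30_000 + (1.5 - t0.start_position) / t0.speed
        lo, hi = t0.onset_sample, t0.offset_sample
        peak_s = (lo + np.argmax(env[lo:hi])) / 30_000
        assert abs(peak_s - expect) < 0.002

    def test_identical_centres_identical_timing(self):
        centres = np.tile([[2.0, -2.0]], (4, 1))
        spec = _spec(task_kind="rf", duration=8.0, rf_centres=centres,
                     per_channel_snr=5.0)
        gt = generate_ground_truth(spec)
        from arrayqc.synthetic import evoked_envelope
        np.testing.assert_allclose(evoked_envelope(spec, gt, 1),
                                   evoked_envelope(spec, gt, 2))

    def test_zero_speed_rejected(self):
        spec = _spec(task_kind="rf", duration=8.0, bar_speed=0.0,
                     rf_centres=default_rf_centres(4, 0))
        with pytest.raises(ConfigurationError):
            generate_bar_trials(spec)

    def test_rf_without_centres_rejected(self):
        with pytest.raises(ConfigurationError):
            _spec(task_kind="rf").validate()


class TestSynchrofactPlanting:
    def test_insertion_count_matches_ground_truth(self):
        grp = SynchrofactGroup(members=(1, 2, 3), rate_hz=1.0)
        spec = _spec(duration=30.0, synchrofact_groups=(grp,),
                     nsp_offsets=np.zeros((1, 2), int))
        gt = generate_ground_truth(spec)
        n_planted = gt.synchrofact_counts()[0]
        assert n_planted > 10
        # inserted waveforms appear identically on all members
        tr1 = channel_trace(spec, gt, 1)
        tr2 = channel_trace(spec, gt, 2)
        at = gt.synchrofact_times[0][0]
        seg1 = tr1[at:at + 40] - np.random.default_rng([5, 101, 1]).normal(
            0, 1.0, spec.n_master)[at:at + 40]
        seg2 = tr2[at:at + 40] - np.random.default_rng([5, 101, 2]).normal(
            0, 1.0, spec.n_master)[at:at + 40]
        corr = np.corrcoef(seg1, seg2)[0, 1]
        assert corr > 0.95

    def test_invalid_members_rejected(self):
        with pytest.raises(ConfigurationError):
            _spec(synchrofact_groups=(
                SynchrofactGroup(members=(999,), rate_hz=1.0),)).validate()

    def test_raster_generator_counts(self):
        grp = SynchrofactGroup(members=tuple(range(1, 11)), rate_hz=1.0)
        raster, times = generate_crossing_raster(
            16, 60.0, background_rate_hz=2.0, groups=(grp,), seed=9)
        assert raster.n_electrodes == 16
        n_planted = len(times[0])
        assert 40 <= n_planted <= 80  # Poisson around 60
        # every member contains all planted times
        for i in range(10):
            assert np.isin(times[0], raster.times[i]).mean() > 0.95


class TestSpecValidation:
    def test_bad_task_rejected(self):
        with pytest.raises(ConfigurationError):
            _spec(task_kind="sleep").validate()

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            _spec(duration=0.0).validate()

    def test_noiseless_without_amplitude_rejected(self):
        with pytest.raises(ConfigurationError):
            _spec(task_kind="snr", noise_sd=0.0).validate()

    def test_planted_snr_amplitude_monotone(self, snr_ground_truth):
        # higher planted SNR needs a larger evoked amplitude
        _, gt = snr_ground_truth
        amp = {s: a for s, a in zip(gt.snr, gt.amplitude)}
        assert amp[1] < amp[3] < amp[8]
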
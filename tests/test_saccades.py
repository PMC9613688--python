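"""Saccade detection, trial scoring, aggregation, and the pupil spectrum."""

import dataclasses

import numpy as np
import pytest

from oculosway.protocol import FrameKind, Side, StimulusEvent, build_schedule, get_condition
from oculosway.saccades import (
    ScoreReason,
    aggregate_condition,
    detect_saccades,
    gaze_duration_target,
    pupil_psd,
    score_schedule,
    score_trial,
    TrialScore,
)
from oculosway.simulate import (
    GazeTrace,
    SubjectModel,
    main_sequence_peak_speed,
    simulate_gaze,
)


def make_trace(gaze_h, sample_rate=1000.0, gaze_v=None, valid=None):
    n = len(gaze_h)
    return GazeTrace(
        sample_rate=sample_rate,
        t=np.arange(n) / sample_rate,
        gaze_h=np.asarray(gaze_h, float),
        gaze_v=np.zeros(n) if gaze_v is None else np.asarray(gaze_v, float),
        pupil=np.full(n, 4.0),
        valid=np.ones(n, bool) if valid is None else np.asarray(valid, bool),
    )


def cosine_bell_step(t, t0, T, amplitude):
    phase = np.clip((t - t0) / T, 0.0, 1.0)
    return amplitude * (phase - np.sin(2 * np.pi * phase) / (2 * np.pi))


class TestDetectSaccades:
    def test_single_rightward_saccade(self):
        # 8 deg movement with 350 deg/s raised-cosine peak at 1 kHz
        fs, A = 1000.0, 8.0
        T = 2 * A / 350.0
        t = np.arange(int(fs)) / fs
        x = cosine_bell_step(t, 0.4, T, A)
        events = detect_saccades(make_trace(x, fs))
        assert len(events) == 1
        ev = events[0]
        assert ev.direction is Side.RIGHT
        # onset/offset sit at the refinement-threshold crossings, so a
        # little of the low-velocity tail displacement is excluded
        assert ev.amplitude == pytest.approx(A, abs=0.3)
        assert ev.peak_speed == pytest.approx(350.0, rel=0.02)
        assert ev.t_onset == pytest.approx(0.4, abs=0.008)

    def test_no_motion_no_events(self, rng):
        x = rng.normal(0.0, 0.05, size=1200)
        assert detect_saccades(make_trace(x, 120.0)) == []

    def test_sub_degree_intrusion_filtered(self):
        # 0.5 deg excursion at ~80 deg/s crosses the velocity threshold but
        # fails the 1 deg amplitude rule
        fs, a = 1000.0, 0.5
        T = 2 * a / 80.0
        t = np.arange(int(fs)) / fs
        x = cosine_bell_step(t, 0.3, T, a)
        assert detect_saccades(make_trace(x, fs)) == []

    def test_mirror_symmetry(self):
        fs, A = 500.0, 6.0
        T = 2 * A / 300.0
        t = np.arange(int(fs)) / fs
        x = cosine_bell_step(t, 0.2, T, A) - cosine_bell_step(t, 0.7, T, A)
        fwd = detect_saccades(make_trace(x, fs))
        rev = detect_saccades(make_trace(-x, fs))
        assert len(fwd) == len(rev) == 2
        for a_ev, b_ev in zip(fwd, rev):
            assert a_ev.t_onset == b_ev.t_onset
            assert a_ev.amplitude == pytest.approx(-b_ev.amplitude)
            assert a_ev.peak_speed == pytest.approx(b_ev.peak_speed)
            assert a_ev.direction is b_ev.direction.mirrored()

    def test_amplitude_floor_is_hard(self, rng):
        """No detected event ever has |amplitude| < 1 deg."""
        subject = SubjectModel(intrusion_rate=2.0, gaze_noise_sd=0.1)
        schedule = build_schedule("2D-P", seed=0)
        trace, _ = simulate_gaze(schedule, subject, 120.0, seed=4)
        for ev in detect_saccades(trace):
            assert abs(ev.amplitude) >= 1.0

    def test_non_uniform_sampling_rejected(self):
        tr = make_trace(np.zeros(100), 100.0)
        tr.t[50] += 0.004
        with pytest.raises(ValueError):
            detect_saccades(tr)

    def test_empty_and_invalid_traces(self):
        assert detect_saccades(make_trace([], 100.0)) == []
        tr = make_trace(np.zeros(100), 100.0, valid=np.zeros(100, bool))
        assert detect_saccades(tr) == []


class TestGazeDurationTarget:
    def test_longest_dwell_wins(self):
        fs = 100.0
        x = np.concatenate([np.full(40, 8.0), np.full(120, -8.0), np.full(40, 0.0)])
        res = gaze_duration_target(make_trace(x, fs), (0.0, 2.0))
        assert res.side is Side.LEFT
        assert res.dwell_left == pytest.approx(1.2)
        assert res.dwell_right == pytest.approx(0.4)
        assert not res.tie

    def test_centre_gaze_is_none(self):
        res = gaze_duration_target(make_trace(np.zeros(200), 100.0), (0.0, 2.0))
        assert res.side is Side.NONE and not res.tie

    def test_equal_dwell_ties(self):
        x = np.concatenate([np.full(50, 8.0), np.full(50, -8.0), np.full(100, 0.0)])
        res = gaze_duration_target(make_trace(x, 100.0), (0.0, 2.0))
        assert res.side is Side.NONE and res.tie

    def test_overlapping_rois_rejected(self):
        with pytest.raises(ValueError):
            gaze_duration_target(make_trace(np.zeros(100), 100.0), (0.0, 1.0),
                                 left_roi=(-4.0, 2.0), right_roi=(0.0, 4.0))


class TestScoreTrial:
    @staticmethod
    def _response(side=Side.RIGHT, t=1.0, dur=1.0):
        return StimulusEvent(t, FrameKind.TARGET, side, 8.0, is_practice=False,
                             trial_index=0, duration=dur)

    def test_definitional_latency(self):
        cond = get_condition("2D-P")
        fs, A = 1000.0, 8.0
        T = 2 * A / 350.0
        t = np.arange(int(2 * fs)) / fs
        x = cosine_bell_step(t, 1.18, T, A)
        trace = make_trace(x, fs)
        saccades = detect_saccades(trace)
        score = score_trial(self._response(), saccades, cond, trace)
        assert score.valid and score.correct
        # onset detected at the refinement crossing, a few ms into the rise
        assert score.latency == pytest.approx(0.180, abs=0.010)

    def test_anti_error_by_direction(self):
        cond = get_condition("2D-A")
        fs, A = 1000.0, 8.0
        T = 2 * A / 350.0
        t = np.arange(int(2 * fs)) / fs
        x = cosine_bell_step(t, 1.2, T, A)  # stimulus right, saccade right
        trace = make_trace(x, fs)
        score = score_trial(self._response(), detect_saccades(trace), cond, trace)
        assert score.valid
        assert score.correct is False

    def test_anticipatory_invalid(self):
        cond = get_condition("2D-P")
        fs, A = 1000.0, 8.0
        T = 2 * A / 350.0
        t = np.arange(int(2 * fs)) / fs
        x = cosine_bell_step(t, 1.03, T, A)
        trace = make_trace(x, fs)
        score = score_trial(self._response(), detect_saccades(trace), cond, trace)
        assert not score.valid
        assert score.reason is ScoreReason.ANTICIPATORY

    def test_no_saccade(self):
        cond = get_condition("2D-P")
        trace = make_trace(np.zeros(2000), 1000.0)
        score = score_trial(self._response(), [], cond, trace)
        assert not score.valid
        assert score.reason is ScoreReason.NO_SACCADE

    def test_long_gap_invalidates(self):
        cond = get_condition("2D-P")
        valid = np.ones(2000, bool)
        valid[1200:1500] = False  # 300 ms gap inside the window
        trace = make_trace(np.zeros(2000), 1000.0, valid=valid)
        score = score_trial(self._response(), [], cond, trace)
        assert score.reason is ScoreReason.DATA_GAP

    def test_vm_uses_gaze_duration_rule(self, quiet_subject):
        schedule = build_schedule("VM-P", seed=2)
        trace, truth = simulate_gaze(schedule, quiet_subject, 120.0, seed=2)
        scores = score_schedule(schedule, trace)
        assert all(s.valid and s.correct for s in scores)


class TestAggregate:
    def test_error_rate_denominator(self):
        scores = [
            TrialScore(i, 0.2, 300.0, i >= 3, True, ScoreReason.OK)
            for i in range(30)
        ]
        agg = aggregate_condition(scores)
        assert agg.error_rate == pytest.approx(0.10)
        assert agg.n_valid == 30

    def test_constant_latency_sd_zero(self):
        scores = [TrialScore(i, 0.2, 300.0, True, True, ScoreReason.OK)
                  for i in range(3)]
        agg = aggregate_condition(scores)
        assert agg.latency_mean == pytest.approx(0.2)
        assert agg.latency_sd == pytest.approx(0.0)

    def test_invalid_trials_excluded(self):
        scores = [TrialScore(0, 0.2, 300.0, True, True, ScoreReason.OK),
                  TrialScore(1, 0.3, 310.0, False, True, ScoreReason.OK),
                  TrialScore(2, None, None, None, False, ScoreReason.NO_SACCADE)]
        agg = aggregate_condition(scores)
        assert agg.n_valid == 2 and agg.n_trials == 3
        assert agg.error_rate == pytest.approx(0.5)

    def test_zero_valid_flagged(self):
        scores = [TrialScore(0, None, None, None, False, ScoreReason.NO_SACCADE)]
        agg = aggregate_condition(scores)
        assert agg.degenerate
        assert np.isnan(agg.latency_mean)

    def test_round_trip_latency_recovery(self):
        subject = SubjectModel(latency_mean=0.250, latency_sd=0.050,
                               error_prob=0.0, gaze_noise_sd=0.0,
                               intrusion_rate=0.0)
        schedule = build_schedule("2D-P", seed=1)
        trace, _ = simulate_gaze(schedule, subject, 120.0, seed=6)
        agg = aggregate_condition(score_schedule(schedule, trace))
        se = 0.050 / np.sqrt(agg.n_valid)
        # detection quantisation adds at most one sample period
        assert abs(agg.latency_mean - 0.250) < 2 * se + 1.0 / 120.0


class TestPupilPsd:
    def test_sinusoid_peak_and_parseval(self):
        fs, f0, amp = 120.0, 0.5, 0.1
        t = np.arange(int(120 * fs)) / fs
        p = 4.0 + amp * np.sin(2 * np.pi * f0 * t)
        res = pupil_psd(p, fs)
        assert res.frequencies[np.argmax(res.psd)] == pytest.approx(f0, abs=0.05)
        integral = np.trapezoid(res.psd, res.frequencies)
        assert integral == pytest.approx(amp ** 2 / 2, rel=0.01)

    def test_constant_series_zero(self):
        res = pupil_psd(np.full(4000, 4.0), 120.0)
        assert res.band_mean == 0.0
        assert np.all(res.psd == 0.0)

    def test_white_noise_parseval_and_flatness(self, rng):
        x = rng.normal(0, 0.3, size=20000)
        res = pupil_psd(x, 100.0)
        integral = np.trapezoid(res.psd, res.frequencies)
        assert integral == pytest.approx(x.var(), rel=0.01)
        # flat spectrum: band means of lower/upper halves agree within 15%
        f = res.frequencies
        lo = res.psd[(f > 1) & (f < 25)].mean()
        hi = res.psd[(f >= 25) & (f < 49)].mean()
        assert lo == pytest.approx(hi, rel=0.15)
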
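"""Saccade detection, trial scoring, condition aggregation, and pupil PSD.

Detection follows the standard velocity-threshold scheme: angular speed from
central differences (lightly smoothed), contiguous supra-threshold intervals
of sufficient duration become candidate events, onsets/offsets are refined
to the nearest sub-threshold samples, and any event whose horizontal
amplitude stays below 1 degree is discarded as a non-saccadic intrusion.

Trial scoring implements the task rules: latency is measured from the
response-frame onset to the onset of the first qualifying saccade;
anticipatory onsets (< 80 ms by default) invalidate the trial; correctness
is by direction for pro/anti trials, and by the gaze-duration rule (the
region of interest with the longest dwell is the selected target) in the
visuospatial-memory and spatial-orientation environments.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import welch

from .protocol import (
    Condition,
    Environment,
    FrameKind,
    OculomotorTask,
    Side,
    StimulusEvent,
    StimulusSchedule,
    expected_direction,
)
from .simulate import GazeTrace

__all__ = [
    "SaccadeEvent",
    "TrialScore",
    "ScoreReason",
    "ConditionOculometrics",
    "GazeDurationResult",
    "detect_saccades",
    "gaze_duration_target",
    "score_trial",
    "score_schedule",
    "aggregate_condition",
    "pupil_psd",
    "PupilPsd",
]

MIN_SACCADE_AMPLITUDE_DEG = 1.0  # below this the movement is non-saccadic
DEFAULT_VELOCITY_THRESHOLD = 30.0   # deg/s
DEFAULT_MIN_DURATION_S = 0.010
DEFAULT_ANTICIPATION_FLOOR_S = 0.080
DEFAULT_ROI_HALF_WIDTH_DEG = 3.0
MAX_INTERP_GAP_S = 0.100


class ScoreReason(str, Enum):
    OK = "ok"
    NO_SACCADE = "no_saccade"
    ANTICIPATORY = "anticipatory"
    DATA_GAP = "data_gap"


@dataclass(frozen=True)
class SaccadeEvent:
    t_onset: float
    t_offset: float
    amplitude: float    # signed deg, + = right
    peak_speed: float   # deg/s
    direction: Side


@dataclass(frozen=True)
class TrialScore:
    trial_index: int
    latency: float | None
    peak_speed: float | None
    correct: bool | None
    valid: bool
    reason: ScoreReason
    #: correctness by first-saccade direction (always recorded; for VM/SO
    #: the authoritative `correct` uses the gaze-duration rule instead)
    correct_by_direction: bool | None = None


@dataclass(frozen=True)
class ConditionOculometrics:
    latency_mean: float
    latency_sd: float
    peak_speed_mean: float
    peak_speed_sd: float
    error_rate: float
    n_valid: int
    n_trials: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "latency_mean": self.latency_mean,
            "latency_sd": self.latency_sd,
            "peak_speed_mean": self.peak_speed_mean,
            "peak_speed_sd": self.peak_speed_sd,
            "error_rate": self.error_rate,
            "n_valid": self.n_valid,
        }


def _interpolate_invalid(trace: GazeTrace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly bridge invalid gaps up to MAX_INTERP_GAP_S.

    Returns (gaze_h, gaze_v, long_gap_mask) where long_gap_mask marks
    samples inside gaps too long to interpolate.
    """
    valid = trace.valid.astype(bool)
    if valid.all():
        return trace.gaze_h, trace.gaze_v, np.zeros(len(valid), dtype=bool)
    max_gap = int(round(MAX_INTERP_GAP_S * trace.sample_rate))
    long_gap = np.zeros(len(valid), dtype=bool)
    # identify runs of invalid samples
    idx = np.flatnonzero(np.diff(np.concatenate(([True], valid, [True])).astype(int)))
    gh, gv = trace.gaze_h.copy(), trace.gaze_v.copy()
    vi = np.flatnonzero(valid)
    if len(vi) == 0:
        return gh, gv, np.ones(len(valid), dtype=bool)
    for start, stop in zip(idx[::2], idx[1::2]):  # invalid runs [start, stop)
        if stop - start > max_gap or start == 0 or stop == len(valid):
            long_gap[start:stop] = True
    fill = ~valid & ~long_gap
    if fill.any():
        gh[fill] = np.interp(trace.t[fill], trace.t[valid], trace.gaze_h[valid])
        gv[fill] = np.interp(trace.t[fill], trace.t[valid], trace.gaze_v[valid])
    return gh, gv, long_gap


def _angular_speed(gh: np.ndarray, gv: np.ndarray, fs: float,
                   smooth: int = 5) -> np.ndarray:
    """Angular speed from central differences.

    Each velocity component is smoothed with a centred ``smooth``-sample
    moving average before taking the magnitude: smoothing the components
    (not the speed) keeps the noise floor zero-mean instead of Rayleigh,
    which matters when position noise puts two-point differences near the
    detection threshold.
    """
    vh = np.gradient(gh) * fs
    vv = np.gradient(gv) * fs
    if smooth > 1 and len(vh) >= smooth:
        kernel = np.ones(smooth) / smooth
        vh = np.convolve(vh, kernel, mode="same")
        vv = np.convolve(vv, kernel, mode="same")
    return np.hypot(vh, vv)


def detect_saccades(
    trace: GazeTrace,
    velocity_threshold: float = DEFAULT_VELOCITY_THRESHOLD,
    min_duration: float = DEFAULT_MIN_DURATION_S,
) -> list[SaccadeEvent]:
    """Velocity-threshold saccade detection with the 1-degree amplitude rule.

    Candidate events are maximal runs of samples with angular speed at or
    above ``velocity_threshold`` lasting at least ``min_duration``; each is
    extended outward to the nearest sub-threshold samples, and events whose
    signed horizontal amplitude is below 1 degree in magnitude are dropped.
    """
    if velocity_threshold <= 0:
        raise ValueError("velocity_threshold must be > 0")
    n = len(trace.t)
    if n < 3 or not trace.valid.any():
        return []
    dt = np.diff(trace.t)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace is not uniformly sampled")

    gh, gv, long_gap = _interpolate_invalid(trace)
    # candidate runs on the smoothed speed (noise-robust); onsets/offsets
    # and the peak refined on the raw two-point speed (no phase smearing)
    speed = np.where(long_gap, 0.0, _angular_speed(gh, gv, trace.sample_rate))
    raw = np.where(long_gap, 0.0, _angular_speed(gh, gv, trace.sample_rate,
                                                 smooth=1))

    above = speed >= velocity_threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(int)))
    min_samples = max(1, int(np.ceil(min_duration * trace.sample_rate)))

    events: list[SaccadeEvent] = []
    last_offset = -1
    for start, stop in zip(edges[::2], edges[1::2]):  # runs [start, stop)
        if stop - start < min_samples:
            continue
        peak = start + int(np.argmax(raw[start:stop]))
        # walk outward from the peak to the nearest raw sub-threshold
        # samples; the refinement threshold adapts to the event's peak so
        # that position-noise excursions near the base threshold do not
        # drag the onset into the preceding fixation
        thr = max(velocity_threshold, 0.2 * float(raw[peak]))
        onset = peak
        while onset > 0 and raw[onset - 1] >= thr:
            onset -= 1
        if onset > 0:
            onset -= 1  # last sub-threshold sample before the crossing
        offset = peak
        while offset < n - 1 and raw[offset + 1] >= thr:
            offset += 1
        if offset < n - 1:
            offset += 1  # first sub-threshold sample after the crossing
        if onset <= last_offset:  # merged with the previous event
            continue
        amplitude = float(gh[offset] - gh[onset])
        if abs(amplitude) < MIN_SACCADE_AMPLITUDE_DEG:
            continue
        last_offset = offset
        events.append(
            SaccadeEvent(
                t_onset=float(trace.t[onset]),
                t_offset=float(trace.t[offset]),
                amplitude=amplitude,
                peak_speed=float(raw[onset:offset + 1].max()),
                direction=Side.RIGHT if amplitude > 0 else Side.LEFT,
            )
        )
    events.sort(key=lambda e: e.t_onset)
    return events


class GazeDurationResult(NamedTuple):
    side: Side
    dwell_left: float
    dwell_right: float
    tie: bool


def gaze_duration_target(
    gaze: GazeTrace,
    response_window: tuple[float, float],
    left_roi: tuple[float, float] = (-11.0, -5.0),
    right_roi: tuple[float, float] = (5.0, 11.0),
) -> GazeDurationResult:
    """Which lateral region of interest the gaze dwelt in longest.

    The target the participant selected is taken to be the side whose ROI
    accumulates the strictly longest dwell time inside the response window;
    equal nonzero dwell is a tie (side NONE, tie flag set).
    """
    if max(left_roi) > min(right_roi) and max(right_roi) > min(left_roi):
        raise ValueError("left and right ROIs overlap")
    t0, t1 = response_window
    if t0 < gaze.t[0] - 1e-9 or t1 > gaze.t[-1] + 1.0 / gaze.sample_rate + 1e-9:
        raise ValueError("response window outside trace span")
    sel = (gaze.t >= t0) & (gaze.t < t1) & gaze.valid
    gh = gaze.gaze_h[sel]
    dt = 1.0 / gaze.sample_rate
    dwell_l = float(np.count_nonzero((gh >= left_roi[0]) & (gh <= left_roi[1])) * dt)
    dwell_r = float(np.count_nonzero((gh >= right_roi[0]) & (gh <= right_roi[1])) * dt)
    if dwell_l == 0.0 and dwell_r == 0.0:
        return GazeDurationResult(Side.NONE, dwell_l, dwell_r, False)
    if dwell_l == dwell_r:
        return GazeDurationResult(Side.NONE, dwell_l, dwell_r, True)
    side = Side.LEFT if dwell_l > dwell_r else Side.RIGHT
    return GazeDurationResult(side, dwell_l, dwell_r, False)


def score_trial(
    response_event: StimulusEvent,
    saccades: Sequence[SaccadeEvent],
    condition: Condition,
    gaze: GazeTrace,
    *,
    anticipation_floor: float = DEFAULT_ANTICIPATION_FLOOR_S,
    roi_half_width: float = DEFAULT_ROI_HALF_WIDTH_DEG,
) -> TrialScore:
    """Score one trial from its response-frame onset.

    The scoring saccade is the first detected saccade with onset inside the
    response window; its latency and peak speed are the trial's oculometrics.
    Onsets earlier than ``anticipation_floor`` after the frame onset mark
    the trial invalid (predictive, not reactive).  Correctness is by
    direction sign for pro/anti trials in 2D/3D; in VM/SO the gaze-duration
    rule is authoritative (first-saccade correctness is recorded alongside).
    """
    t0 = response_event.t_onset
    t1 = t0 + response_event.duration
    expected = expected_direction(condition, response_event)

    # data-gap check: any un-interpolatable invalid samples in the window
    sel = (gaze.t >= t0) & (gaze.t < t1)
    if sel.any():
        _, _, long_gap = _interpolate_invalid(gaze)
        if long_gap[sel].any():
            return TrialScore(response_event.trial_index, None, None, None,
                              False, ScoreReason.DATA_GAP)

    in_window = [s for s in saccades if t0 <= s.t_onset < t1]
    if not in_window:
        return TrialScore(response_event.trial_index, None, None, None,
                          False, ScoreReason.NO_SACCADE)
    first = in_window[0]
    latency = first.t_onset - t0
    if latency < anticipation_floor:
        return TrialScore(response_event.trial_index, None, None, None,
                          False, ScoreReason.ANTICIPATORY)

    correct_dir = first.direction is expected
    env = condition.environment
    if env in (Environment.VM, Environment.SO):
        ecc = response_event.eccentricity
        res = gaze_duration_target(
            gaze, (t0, t1),
            left_roi=(-ecc - roi_half_width, -ecc + roi_half_width),
            right_roi=(ecc - roi_half_width, ecc + roi_half_width),
        )
        correct = res.side is expected
    else:
        correct = correct_dir
    return TrialScore(
        trial_index=response_event.trial_index,
        latency=latency,
        peak_speed=first.peak_speed,
        correct=correct,
        valid=True,
        reason=ScoreReason.OK,
        correct_by_direction=correct_dir,
    )


def score_schedule(
    schedule: StimulusSchedule,
    gaze: GazeTrace,
    *,
    velocity_threshold: float = DEFAULT_VELOCITY_THRESHOLD,
    min_duration: float = DEFAULT_MIN_DURATION_S,
    anticipation_floor: float = DEFAULT_ANTICIPATION_FLOOR_S,
    roi_half_width: float = DEFAULT_ROI_HALF_WIDTH_DEG,
    recorded_only: bool = True,
) -> list[TrialScore]:
    """Detect saccades once and score every (recorded) trial of a schedule."""
    saccades = detect_saccades(gaze, velocity_threshold, min_duration)
    scores = []
    for ev in schedule.response_events(recorded_only=recorded_only):
        scores.append(
            score_trial(ev, saccades, schedule.condition, gaze,
                        anticipation_floor=anticipation_floor,
                        roi_half_width=roi_half_width)
        )
    return scores


def aggregate_condition(scores: Sequence[TrialScore]) -> ConditionOculometrics:
    """Mean/SD latency and peak speed plus error rate over valid trials.

    Error rate uses valid trials as the denominator; sample SDs use the
    n-1 denominator.  With no valid trials the summary is flagged
    degenerate and filled with NaN.
    """
    valid = [s for s in scores if s.valid]
    if not valid:
        nan = float("nan")
        return ConditionOculometrics(nan, nan, nan, nan, nan, 0, len(scores),
                                     degenerate=True)
    lat = np.array([s.latency for s in valid if s.latency is not None])
    spd = np.array([s.peak_speed for s in valid if s.peak_speed is not None])
    n_err = sum(1 for s in valid if s.correct is False)
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) >= 2 else float("nan")
    return ConditionOculometrics(
        latency_mean=float(lat.mean()) if len(lat) else float("nan"),
        latency_sd=sd(lat),
        peak_speed_mean=float(spd.mean()) if len(spd) else float("nan"),
        peak_speed_sd=sd(spd),
        error_rate=n_err / len(valid),
        n_valid=len(valid),
        n_trials=len(scores),
    )


class PupilPsd(NamedTuple):
    frequencies: np.ndarray   # Hz
    psd: np.ndarray           # mm^2/Hz, integrates to series variance
    band_mean: float          # mm^2/Hz over the configured band


def pupil_psd(
    pupil: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = (0.05, 2.0),
    nperseg: int | None = None,
) -> PupilPsd:
    """Variance-normalised Welch spectrum of the de-trended pupil series.

    The averaged periodogram is rescaled so its trapezoidal integral over
    frequency equals the variance of the linearly de-trended series
    (Parseval convention); ``band_mean`` is the mean density over ``band``.
    A constant series yields an all-zero spectrum.
    """
    pupil = np.asarray(pupil, dtype=float)
    if nperseg is None:
        nperseg = min(len(pupil), max(256, int(8 * sample_rate)))
    f, pxx = welch(pupil, fs=sample_rate, nperseg=min(nperseg, len(pupil)),
                   detrend="linear")
    # remove the series-level linear trend before computing target variance
    t = np.arange(len(pupil))
    resid = pupil - np.polyval(np.polyfit(t, pupil, 1), t)
    var = float(resid.var())
    integral = float(np.trapezoid(pxx, f))
    scale = max(1.0, float(np.abs(pupil).max()))
    if var <= (1e-10 * scale) ** 2 or integral <= 0:  # constant series
        pxx = np.zeros_like(pxx)
    else:
        pxx = pxx * (var / integral)
    in_band = (f >= band[0]) & (f <= band[1])
    band_mean = float(pxx[in_band].mean()) if in_band.any() else 0.0
    return PupilPsd(f, pxx, band_mean)
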
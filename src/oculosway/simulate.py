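"""Synthetic gaze / pupil / centre-of-pressure recordings with ground truth.

No public dataset of concurrent VR oculometry + posturography exists, so the
package ships a simulator: every downstream stage (saccade detection, trial
scoring, posturography, statistics) is exercised against recordings whose
per-trial latencies, directions, and sway moments are known exactly.

The gaze model is deliberately simple but physiologically shaped:

* trial latencies follow a shifted log-normal law with an 80 ms floor
  (reactive saccades cannot be faster);
* each saccade has a raised-cosine velocity profile, so the position trace
  is sigmoidal and the peak speed is exactly the main-sequence value
  ``vmax * (1 - exp(-amplitude / c))``;
* sub-1-degree saccadic intrusions are injected as a Poisson process of
  small out-and-back excursions;
* additive white gaze noise.

The centre of pressure is modelled per axis as a stationary mean-reverting
(Ornstein-Uhlenbeck) process with relaxation rate ``theta`` (1/s) and
diffusion ``D`` (mm^2/s); its stationary SD is ``sqrt(D / (2 theta))``,
giving an analytic target for the posturography metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .protocol import (
    FrameKind,
    OculomotorTask,
    Side,
    StimulusSchedule,
    expected_direction,
)

__all__ = [
    "SubjectModel",
    "GazeTrace",
    "CopTrace",
    "TrialTruth",
    "GazeGroundTruth",
    "main_sequence_peak_speed",
    "saccade_duration",
    "simulate_gaze",
    "simulate_cop",
    "simulate_pupil",
]

LATENCY_FLOOR_S = 0.080

DEFAULT_GAZE_RATE_HZ = 120.0
DEFAULT_COP_RATE_HZ = 100.0


@dataclass(frozen=True)
class SubjectModel:
    """Generative parameters for one synthetic participant.

    Defaults describe a healthy older adult in the baseline dual-task
    condition: ~250 ms mean saccade latency with 50 ms spread, 10% direction
    errors, a conventional main sequence saturating at 500 deg/s, a few
    small intrusions per minute, and quiet-stance sway of ~2 mm stationary
    SD per axis.
    """

    latency_mean: float = 0.250      # s
    latency_sd: float = 0.050        # s
    error_prob: float = 0.10
    main_sequence_vmax: float = 500.0  # deg/s
    main_sequence_c: float = 6.0       # deg
    intrusion_rate: float = 0.05       # events/s, amplitude < 1 deg
    gaze_noise_sd: float = 0.10        # deg
    cop_relaxation: float = 1.0        # 1/s
    cop_diffusion: float = 8.0         # mm^2/s
    pupil_base: float = 4.0            # mm
    pupil_osc_amp: float = 0.10        # mm
    pupil_osc_freq: float = 0.5        # Hz
    pupil_noise_sd: float = 0.02       # mm
    field_of_view: float = 55.0        # deg, |gaze| clip bound

    def __post_init__(self):
        if not (0.0 <= self.error_prob <= 1.0):
            raise ValueError("error_prob must lie in [0, 1]")
        for name in ("latency_sd", "intrusion_rate", "gaze_noise_sd",
                     "pupil_osc_amp", "pupil_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.latency_mean < 0:
            raise ValueError("latency_mean must be >= 0")


@dataclass
class GazeTrace:
    """Uniformly sampled gaze angles (deg), pupil diameter (mm), validity."""

    sample_rate: float
    t: np.ndarray
    gaze_h: np.ndarray   # + = right
    gaze_v: np.ndarray   # + = up
    pupil: np.ndarray
    valid: np.ndarray

    @property
    def duration(self) -> float:
        return len(self.t) / self.sample_rate


@dataclass
class CopTrace:
    """Uniformly sampled 2-D centre-of-pressure positions (mm)."""

    sample_rate: float
    t: np.ndarray
    x_ml: np.ndarray   # medio-lateral, + = right
    y_ap: np.ndarray   # anterior-posterior, + = anterior

    @property
    def duration(self) -> float:
        return len(self.t) / self.sample_rate


@dataclass(frozen=True)
class TrialTruth:
    trial_index: int
    is_practice: bool
    t_response_onset: float
    latency: float
    direction: Side
    correct: bool
    amplitude: float      # signed deg
    peak_speed: float     # deg/s
    expected: Side


@dataclass
class GazeGroundTruth:
    trials: list[TrialTruth]
    n_latency_redraws: int = 0
    n_intrusions: int = 0

    def recorded(self) -> list[TrialTruth]:
        return [t for t in self.trials if not t.is_practice]


def main_sequence_peak_speed(amplitude_deg: float, vmax: float, c: float) -> float:
    """Saturating amplitude / peak-velocity law: vmax * (1 - exp(-A/c))."""
    return vmax * (1.0 - np.exp(-abs(amplitude_deg) / c))


def saccade_duration(amplitude_deg: float, vmax: float, c: float) -> float:
    """Duration of a raised-cosine saccade with main-sequence peak speed.

    For velocity v(t) = (A/T) (1 - cos(2 pi t / T)), the peak is 2A/T, so
    T = 2|A| / v_peak.
    """
    vp = main_sequence_peak_speed(amplitude_deg, vmax, c)
    return 2.0 * abs(amplitude_deg) / vp


def _cosine_bell_positions(t: np.ndarray, t0: float, T: float, a: float) -> np.ndarray:
    """Displacement profile of a raised-cosine-velocity movement.

    Zero before t0, ``a`` after t0+T, sigmoidal in between.
    """
    phase = np.clip((t - t0) / T, 0.0, 1.0)
    return a * (phase - np.sin(2.0 * np.pi * phase) / (2.0 * np.pi))


def _draw_latency(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Shifted log-normal latency with floor LATENCY_FLOOR_S."""
    if sd == 0.0:
        return mean
    shifted = mean - LATENCY_FLOOR_S
    if shifted <= 0:
        raise ValueError(
            f"latency_mean must exceed the {LATENCY_FLOOR_S*1e3:.0f} ms floor "
            "when latency_sd > 0"
        )
    sigma2 = np.log1p((sd / shifted) ** 2)
    mu = np.log(shifted) - sigma2 / 2.0
    return LATENCY_FLOOR_S + float(rng.lognormal(mu, np.sqrt(sigma2)))


class _MovementList:
    """Chronological, non-overlapping eye movements rendered onto a grid."""

    def __init__(self, t: np.ndarray):
        self.t = t
        self.moves: list[tuple[float, float, float]] = []  # (t0, T, amplitude)

    def last_end(self) -> float:
        if not self.moves:
            return -np.inf
        t0, T, _ = self.moves[-1]
        return t0 + T

    def add(self, t0: float, T: float, amplitude: float, min_gap: float = 0.02) -> bool:
        if t0 < self.last_end() + min_gap:
            return False
        self.moves.append((t0, T, amplitude))
        return True

    def render(self) -> np.ndarray:
        x = np.zeros_like(self.t)
        for t0, T, a in self.moves:
            x += _cosine_bell_positions(self.t, t0, T, a)
        return x


def simulate_gaze(
    schedule: StimulusSchedule,
    subject: SubjectModel,
    sample_rate: float = DEFAULT_GAZE_RATE_HZ,
    seed: int = 0,
) -> tuple[GazeTrace, GazeGroundTruth]:
    """Simulate a gaze recording for one condition.

    Every trial (practice included) contains one primary saccade whose onset
    is the response-frame onset plus a latency draw, directed correctly with
    probability ``1 - error_prob`` (errors go to the mirrored side); the eye
    dwells on the landing position until the next fixation frame, then a
    return saccade brings it back to centre.  Per-trial ground truth is
    returned for recovery tests.
    """
    if sample_rate < 60.0:
        raise ValueError("sample_rate must be >= 60 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(schedule.total_duration * sample_rate))
    t = np.arange(n) / sample_rate

    moves = _MovementList(t)
    truths: list[TrialTruth] = []
    n_redraws = 0
    vmax, c = subject.main_sequence_vmax, subject.main_sequence_c
    has_task = schedule.condition.oculomotor_task in (
        OculomotorTask.PRO, OculomotorTask.ANTI
    )

    if has_task:
        for ev in schedule.response_events(recorded_only=False):
            window = ev.duration
            amp_abs = ev.eccentricity
            T_sacc = saccade_duration(amp_abs, vmax, c)
            # latency must leave the saccade inside the response window
            latency = _draw_latency(rng, subject.latency_mean, subject.latency_sd)
            limit = window - T_sacc - 0.05
            while latency > limit:
                n_redraws += 1
                latency = _draw_latency(rng, subject.latency_mean, subject.latency_sd)
                if subject.latency_sd == 0.0:
                    raise ValueError(
                        "deterministic latency exceeds the response window"
                    )
            expected = expected_direction(schedule.condition, ev)
            correct = rng.random() >= subject.error_prob
            direction = expected if correct else expected.mirrored()
            signed_amp = amp_abs if direction is Side.RIGHT else -amp_abs
            t_on = ev.t_onset + latency
            moves.add(t_on, T_sacc, signed_amp, min_gap=0.0)
            # return to centre at the next fixation onset
            moves.add(ev.t_onset + window, T_sacc, -signed_amp, min_gap=0.0)
            truths.append(
                TrialTruth(
                    trial_index=ev.trial_index,
                    is_practice=ev.is_practice,
                    t_response_onset=ev.t_onset,
                    latency=latency,
                    direction=direction,
                    correct=correct,
                    amplitude=signed_amp,
                    peak_speed=main_sequence_peak_speed(amp_abs, vmax, c),
                    expected=expected,
                )
            )

    gaze_h = moves.render()

    # saccadic intrusions: small out-and-back excursions, Poisson in time
    n_intr = 0
    if subject.intrusion_rate > 0:
        n_events = rng.poisson(subject.intrusion_rate * schedule.total_duration)
        starts = np.sort(rng.uniform(0.0, schedule.total_duration, size=n_events))
        intr = _MovementList(t)
        for t0 in starts:
            a = rng.uniform(0.3, 0.9) * (1 if rng.random() < 0.5 else -1)
            T_i = saccade_duration(a, vmax, c)
            if intr.add(t0, T_i, a, min_gap=0.1):
                intr.add(t0 + T_i + 0.1, T_i, -a, min_gap=0.0)
                n_intr += 1
        gaze_h = gaze_h + intr.render()

    if subject.gaze_noise_sd > 0:
        gaze_h = gaze_h + rng.normal(0.0, subject.gaze_noise_sd, size=n)
    gaze_v = (rng.normal(0.0, subject.gaze_noise_sd, size=n)
              if subject.gaze_noise_sd > 0 else np.zeros(n))
    np.clip(gaze_h, -subject.field_of_view, subject.field_of_view, out=gaze_h)

    pupil = _pupil_series(t, subject, rng)
    trace = GazeTrace(
        sample_rate=sample_rate,
        t=t,
        gaze_h=gaze_h,
        gaze_v=gaze_v,
        pupil=pupil,
        valid=np.ones(n, dtype=bool),
    )
    truth = GazeGroundTruth(trials=truths, n_latency_redraws=n_redraws,
                            n_intrusions=n_intr)
    return trace, truth


def simulate_cop(
    duration: float,
    subject: SubjectModel,
    sample_rate: float = DEFAULT_COP_RATE_HZ,
    seed: int = 0,
) -> CopTrace:
    """Stationary mean-reverting sway per axis, exact discretization.

    x_{k+1} = x_k e^{-theta dt} + sigma_inf sqrt(1 - e^{-2 theta dt}) xi_k
    with sigma_inf = sqrt(D / (2 theta)); initial state drawn from the
    stationary law so the whole trace is stationary.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    theta, D = subject.cop_relaxation, subject.cop_diffusion
    if D < 0:
        raise ValueError("cop_diffusion must be >= 0")
    if D > 0 and theta <= 0:
        raise ValueError("non-stationary sway: cop_relaxation must be > 0 "
                         "when cop_diffusion > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    if D == 0:
        zero = np.zeros(n)
        return CopTrace(sample_rate, t, zero, zero.copy())

    dt = 1.0 / sample_rate
    decay = np.exp(-theta * dt)
    sigma_inf = np.sqrt(D / (2.0 * theta))
    step_sd = sigma_inf * np.sqrt(1.0 - decay ** 2)

    drive = rng.normal(size=(2, n)) * step_sd
    drive[:, 0] = rng.normal(size=2) * sigma_inf  # stationary start
    # AR(1): x[k] = decay x[k-1] + drive[k]
    out = lfilter([1.0], [1.0, -decay], drive, axis=1)
    return CopTrace(sample_rate, t, out[0], out[1])


def _pupil_series(t: np.ndarray, subject: SubjectModel,
                  rng: np.random.Generator) -> np.ndarray:
    p = subject.pupil_base + subject.pupil_osc_amp * np.sin(
        2.0 * np.pi * subject.pupil_osc_freq * t
    )
    if subject.pupil_noise_sd > 0:
        p = p + rng.normal(0.0, subject.pupil_noise_sd, size=len(t))
    return p


def simulate_pupil(
    duration: float,
    subject: SubjectModel,
    sample_rate: float = DEFAULT_GAZE_RATE_HZ,
    seed: int = 0,
) -> np.ndarray:
    """Pupil diameter series (mm): base + sinusoid + white noise."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    return _pupil_series(t, subject, rng)
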
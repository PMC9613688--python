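"""Posturography: centre-of-pressure sway metrics.

Three families of stabilometric parameters are computed from the 2-D COP
trajectory: per-axis dispersion (sample SD of the anterior-posterior and
medio-lateral displacement), mean sway speed (path length per unit time,
total and per axis), and the sway area of the envelope curve (AEC) — the
area enclosed by the outer envelope of the trajectory, implemented as the
area of its convex hull (monotone-chain construction, shoelace formula).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .simulate import CopTrace

__all__ = [
    "PostureMetrics",
    "compute_posture_metrics",
    "convex_envelope_area",
    "convex_hull",
]


@dataclass(frozen=True)
class PostureMetrics:
    sd_ap: float        # mm
    sd_ml: float        # mm
    speed_total: float  # mm/s
    speed_ap: float     # mm/s
    speed_ml: float     # mm/s
    aec: float          # mm^2
    duration: float     # s
    degenerate: bool = False   # hull had < 3 non-collinear points

    def as_dict(self) -> dict:
        return {
            "sd_ap": self.sd_ap, "sd_ml": self.sd_ml,
            "speed_total": self.speed_total, "speed_ap": self.speed_ap,
            "speed_ml": self.speed_ml, "aec": self.aec,
            "duration": self.duration,
        }


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull by Andrew's monotone chain; vertices counter-clockwise.

    Collinear boundary points are excluded.  Degenerate inputs (fewer than
    3 distinct non-collinear points) return the distinct points as given.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinates")
    uniq = np.unique(pts, axis=0)  # lexicographic sort
    if len(uniq) <= 2:
        return uniq
    lower: list[np.ndarray] = []
    for p in uniq:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in uniq[::-1]:
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    return np.array(hull)


def convex_envelope_area(points) -> float:
    """Area (mm^2) of the convex envelope of a 2-D point set.

    Shoelace formula over the monotone-chain hull; fewer than 3
    non-collinear points give area 0.
    """
    hull = convex_hull(np.asarray(points, dtype=float))
    if len(hull) < 3:
        return 0.0
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def compute_posture_metrics(
    trace: CopTrace,
    analysis_window: tuple[float, float] | None = None,
    lowpass_hz: float | None = None,
) -> PostureMetrics:
    """Sway metrics over an analysis window of a COP trace.

    ``analysis_window`` is (start, stop) in seconds; None takes the whole
    trace.  ``lowpass_hz`` optionally applies a 4th-order zero-phase
    Butterworth low-pass before the metrics (off by default; platform
    output is assumed conditioned).
    """
    x, y, t = trace.x_ml, trace.y_ap, trace.t
    if analysis_window is not None:
        t0, t1 = analysis_window
        if t0 < t[0] - 1e-9 or t1 > t[-1] + 1.0 / trace.sample_rate + 1e-9:
            raise ValueError("analysis window outside trace span")
        sel = (t >= t0) & (t < t1)
        x, y, t = x[sel], y[sel], t[sel]
    if len(t) < 2:
        raise ValueError("need at least 2 samples in the analysis window")

    if lowpass_hz is not None:
        b, a = butter(4, lowpass_hz, fs=trace.sample_rate)
        x, y = filtfilt(b, a, x), filtfilt(b, a, y)

    duration = (len(t) - 1) / trace.sample_rate  # elapsed time first->last
    dx, dy = np.diff(x), np.diff(y)
    step = np.hypot(dx, dy)
    pts = np.column_stack([x, y])
    hull = convex_hull(pts)
    aec = convex_envelope_area(pts)
    return PostureMetrics(
        sd_ap=float(np.std(y, ddof=1)),
        sd_ml=float(np.std(x, ddof=1)),
        speed_total=float(step.sum() / duration),
        speed_ap=float(np.abs(dy).sum() / duration),
        speed_ml=float(np.abs(dx).sum() / duration),
        aec=aec,
        duration=duration,
        degenerate=len(hull) < 3,
    )
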
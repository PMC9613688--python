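"""File formats and run configuration.

CSV is the canonical trace interchange format.  Files begin with ``#``
metadata lines declaring the sample rate and units, then a header row:

* gaze: ``t, gaze_h, gaze_v, pupil, valid`` (s, deg, deg, mm, 0/1)
* COP:  ``t, x_ml, y_ap`` (s, mm, mm) — a ``# unit=cm`` declaration is
  converted to mm on read.

Schedules and ground truth travel as JSON (see :mod:`oculosway.protocol`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CopTrace, GazeTrace, GazeGroundTruth, TrialTruth
from .protocol import Side

__all__ = [
    "RunConfig",
    "write_gaze_csv", "read_gaze_csv",
    "write_cop_csv", "read_cop_csv",
    "write_ground_truth", "read_ground_truth",
]

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Everything a pipeline run needs; JSON round-trip safe.

    Defaults document themselves: gaze at 120 Hz and COP at 100 Hz
    (configurable device conventions), 30 deg/s velocity threshold with
    10 ms minimum duration, 80 ms anticipation floor, +/-3 deg dwell ROIs,
    Holm adjustment, and the ART factorial variant.
    """

    seed: int = 0
    n_subjects: int = 20
    conditions: list[int] = field(default_factory=lambda: list(range(1, 12)))
    gaze_sample_rate: float = 120.0
    cop_sample_rate: float = 100.0
    velocity_threshold: float = 30.0     # deg/s
    min_saccade_duration: float = 0.010  # s
    anticipation_floor: float = 0.080    # s
    roi_half_width: float = 3.0          # deg
    pupil_band: tuple[float, float] = (0.05, 2.0)  # Hz
    adjust_method: str = "holm"          # holm | bonferroni | bh
    anova_variant: str = "art"           # art | friedman
    cop_unit: str = "mm"

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["pupil_band"] = list(self.pupil_band)
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        payload["pupil_band"] = tuple(payload.get("pupil_band", (0.05, 2.0)))
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# trace CSV
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path, meta: dict) -> None:
    with open(path, "w", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_csv(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def _check_time(df: pd.DataFrame, path) -> None:
    t = df["t"].to_numpy()
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: time column not strictly increasing at row {bad[0] + 2}"
        )


def _check_rate(df: pd.DataFrame, rate: float, path) -> None:
    t = df["t"].to_numpy()
    if len(t) < 2:
        return
    implied = (len(t) - 1) / (t[-1] - t[0])
    if abs(implied - rate) / rate > 1e-3:
        warnings.warn(
            f"{path}: declared rate {rate} Hz but data imply {implied:.4f} Hz",
            stacklevel=3,
        )


def write_gaze_csv(trace: GazeTrace, path) -> None:
    df = pd.DataFrame({
        "t": trace.t, "gaze_h": trace.gaze_h, "gaze_v": trace.gaze_v,
        "pupil": trace.pupil, "valid": trace.valid.astype(int),
    })
    _write_csv(df, path, {"sample_rate_hz": trace.sample_rate,
                          "gaze_unit": "deg", "pupil_unit": "mm"})


def read_gaze_csv(path) -> GazeTrace:
    df, meta = _read_csv(path)
    required = {"t", "gaze_h", "gaze_v", "pupil", "valid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    _check_time(df, path)
    rate = float(meta.get("sample_rate_hz", 0)) or (len(df) - 1) / (
        df["t"].iloc[-1] - df["t"].iloc[0]
    )
    _check_rate(df, rate, path)
    return GazeTrace(
        sample_rate=rate,
        t=df["t"].to_numpy(float),
        gaze_h=df["gaze_h"].to_numpy(float),
        gaze_v=df["gaze_v"].to_numpy(float),
        pupil=df["pupil"].to_numpy(float),
        valid=df["valid"].to_numpy().astype(bool),
    )


def write_cop_csv(trace: CopTrace, path, unit: str = "mm") -> None:
    scale = {"mm": 1.0, "cm": 0.1}[unit]
    df = pd.DataFrame({"t": trace.t, "x_ml": trace.x_ml * scale,
                       "y_ap": trace.y_ap * scale})
    _write_csv(df, path, {"sample_rate_hz": trace.sample_rate, "unit": unit})


def read_cop_csv(path) -> CopTrace:
    df, meta = _read_csv(path)
    missing = {"t", "x_ml", "y_ap"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    _check_time(df, path)
    unit = meta.get("unit", "mm")
    scale = {"mm": 1.0, "cm": 10.0}.get(unit)
    if scale is None:
        raise ValueError(f"{path}: unknown COP unit {unit!r}")
    rate = float(meta.get("sample_rate_hz", 0)) or (len(df) - 1) / (
        df["t"].iloc[-1] - df["t"].iloc[0]
    )
    _check_rate(df, rate, path)
    return CopTrace(
        sample_rate=rate,
        t=df["t"].to_numpy(float),
        x_ml=df["x_ml"].to_numpy(float) * scale,
        y_ap=df["y_ap"].to_numpy(float) * scale,
    )


# ---------------------------------------------------------------------------
# ground-truth sidecar
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GazeGroundTruth, path) -> None:
    payload = {
        "n_latency_redraws": truth.n_latency_redraws,
        "n_intrusions": truth.n_intrusions,
        "trials": [
            {
                "trial_index": t.trial_index,
                "is_practice": t.is_practice,
                "t_response_onset": t.t_response_onset,
                "latency": t.latency,
                "direction": t.direction.value,
                "correct": t.correct,
                "amplitude": t.amplitude,
                "peak_speed": t.peak_speed,
                "expected": t.expected.value,
            }
            for t in truth.trials
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path) -> GazeGroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    trials = [
        TrialTruth(
            trial_index=rec["trial_index"],
            is_practice=rec["is_practice"],
            t_response_onset=rec["t_response_onset"],
            latency=rec["latency"],
            direction=Side(rec["direction"]),
            correct=rec["correct"],
            amplitude=rec["amplitude"],
            peak_speed=rec["peak_speed"],
            expected=Side(rec["expected"]),
        )
        for rec in payload["trials"]
    ]
    return GazeGroundTruth(trials=trials,
                           n_latency_redraws=payload["n_latency_redraws"],
                           n_intrusions=payload["n_intrusions"])
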
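"""Experimental protocol: conditions, stimulus events, and trial schedules.

The assessment battery crosses four virtual environments (2D, 3D with visual
challenge, visuospatial-memory, spatial-orientation) with pro- and
anti-saccade tasks, plus eyes-open / eyes-closed / gaze-only control
conditions, for 11 conditions in total.  Each saccade condition is a fixed
sequence of cycles; a cycle is a short sequence of stimulus frames
(fixation, then a lateralised target at +/-8 deg, with memorise /
allocentric-view frames in the VM and SO environments).  The first cycles
are unrecorded practice; posture recording starts when the recorded trials
begin.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Environment",
    "OculomotorTask",
    "DualTaskFlag",
    "FrameKind",
    "Side",
    "Symbol",
    "Condition",
    "StimulusEvent",
    "StimulusSchedule",
    "condition_table",
    "get_condition",
    "build_schedule",
    "expected_direction",
    "balanced_sides",
    "schedule_to_json",
    "schedule_from_json",
    "schedule_to_csv",
]


class Environment(str, Enum):
    EO = "EO"
    EC = "EC"
    TWO_D = "2D"
    THREE_D = "3D"
    VM = "VM"
    SO = "SO"


class OculomotorTask(str, Enum):
    NONE = "none"
    GAZE = "gaze"
    PRO = "pro"
    ANTI = "anti"


class DualTaskFlag(str, Enum):
    POSTURE = "posture"
    SACCADE = "saccade"
    VM = "VM"
    SO = "SO"
    VC = "VC"


class FrameKind(str, Enum):
    CENTRAL_FIXATION = "central_fixation"
    TARGET = "target"
    MEMORISE = "memorise"
    ALLOCENTRIC_VIEW = "allocentric_view"
    RESPONSE = "response"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"

    def mirrored(self) -> "Side":
        if self is Side.LEFT:
            return Side.RIGHT
        if self is Side.RIGHT:
            return Side.LEFT
        return Side.NONE


class Symbol(str, Enum):
    CROSS = "cross"
    TRIANGLE = "triangle"
    SQUARE = "square"
    STAR = "star"
    HEART = "heart"
    PENTAGON = "pentagon"
    DISC = "disc"
    NONE = "none"


#: the six memorisable symbols used in the VM environment
VM_SYMBOLS = (
    Symbol.CROSS,
    Symbol.TRIANGLE,
    Symbol.SQUARE,
    Symbol.STAR,
    Symbol.HEART,
    Symbol.PENTAGON,
)

TARGET_ECCENTRICITY_DEG = 8.0
INNER_ECCENTRICITY_DEG = 2.0  # VM symbol / SO allocentric-map eccentricity


@dataclass(frozen=True)
class Condition:
    """One of the 11 experimental conditions."""

    index: int
    name: str
    environment: Environment
    oculomotor_task: OculomotorTask
    dual_task_flags: frozenset[DualTaskFlag]

    @property
    def has_saccade_task(self) -> bool:
        return self.oculomotor_task in (OculomotorTask.PRO, OculomotorTask.ANTI)


@dataclass(frozen=True)
class StimulusEvent:
    """A single stimulus frame onset.

    ``side`` is the lateralisation of the frame's salient stimulus: for
    target/response frames, where the saccade goal (or the cue that defines
    it) is displayed; for memorise frames it is NONE (two symbols shown at
    +/-2 deg, recorded in ``symbols``); for allocentric-view frames it is
    the side of the circle target inside the small map.
    """

    t_onset: float
    frame_kind: FrameKind
    side: Side = Side.NONE
    eccentricity: float = 0.0
    symbol: Symbol = Symbol.NONE
    is_practice: bool = False
    trial_index: int = -1
    duration: float = 0.0
    #: (left symbol, right symbol) for memorise frames
    symbols: tuple[Symbol, Symbol] | None = None


@dataclass
class StimulusSchedule:
    condition: Condition
    events: list[StimulusEvent]
    n_practice: int
    n_recorded: int
    cycle_duration: float
    posture_recording_start: float
    seed: int = 0

    @property
    def n_cycles(self) -> int:
        return self.n_practice + self.n_recorded

    @property
    def total_duration(self) -> float:
        return self.n_cycles * self.cycle_duration

    def response_events(self, recorded_only: bool = True) -> list[StimulusEvent]:
        """Events that open a response window (target frames in 2D/3D,
        response frames in VM/SO)."""
        kinds = (FrameKind.TARGET, FrameKind.RESPONSE)
        out = [e for e in self.events if e.frame_kind in kinds]
        if recorded_only:
            out = [e for e in out if not e.is_practice]
        return out


# --- condition catalogue ---------------------------------------------------

_P, _S, _VM, _SO, _VC = (
    DualTaskFlag.POSTURE,
    DualTaskFlag.SACCADE,
    DualTaskFlag.VM,
    DualTaskFlag.SO,
    DualTaskFlag.VC,
)

_CONDITIONS = (
    Condition(1, "EO", Environment.EO, OculomotorTask.GAZE, frozenset({_P})),
    Condition(2, "EC", Environment.EC, OculomotorTask.NONE, frozenset({_P})),
    Condition(3, "2D-G", Environment.TWO_D, OculomotorTask.GAZE, frozenset({_P})),
    Condition(4, "2D-P", Environment.TWO_D, OculomotorTask.PRO, frozenset({_P, _S})),
    Condition(5, "2D-A", Environment.TWO_D, OculomotorTask.ANTI, frozenset({_P, _S})),
    Condition(6, "3D-P", Environment.THREE_D, OculomotorTask.PRO, frozenset({_P, _S, _VC})),
    Condition(7, "3D-A", Environment.THREE_D, OculomotorTask.ANTI, frozenset({_P, _S, _VC})),
    Condition(8, "VM-P", Environment.VM, OculomotorTask.PRO, frozenset({_P, _S, _VM})),
    Condition(9, "VM-A", Environment.VM, OculomotorTask.ANTI, frozenset({_P, _S, _VM})),
    Condition(10, "SO-P", Environment.SO, OculomotorTask.PRO, frozenset({_P, _S, _SO})),
    Condition(11, "SO-A", Environment.SO, OculomotorTask.ANTI, frozenset({_P, _S, _SO})),
)


def condition_table() -> list[Condition]:
    """The 11 experimental conditions of the concurrent assessment battery."""
    return list(_CONDITIONS)


def get_condition(key: int | str) -> Condition:
    """Look a condition up by index (1..11) or name (e.g. ``"VM-P"``)."""
    for c in _CONDITIONS:
        if c.index == key or c.name == key:
            return c
    raise KeyError(f"unknown condition: {key!r}")


# --- per-environment cycle structure ---------------------------------------

#: (cycle_duration s, n_practice, n_recorded) per environment
_ENV_TIMING = {
    Environment.TWO_D: (2.0, 10, 30),
    Environment.THREE_D: (2.0, 10, 30),
    Environment.VM: (10.0, 5, 15),
    Environment.SO: (7.5, 5, 15),
}

_FRAME_2D3D = 1.0
_FRAME_VMSO = 2.5


def _permute_max_run(base: list[Side], rng: np.random.Generator,
                     max_run: int) -> list[Side]:
    """Seeded permutation of a side multiset with no run longer than
    ``max_run`` (anticipation mitigation); rejection sampling, which for
    near-balanced n <= 30 and max_run 3 accepts quickly."""
    n = len(base)
    for _ in range(10_000):
        perm = rng.permutation(n)
        seq = [base[i] for i in perm]
        run, ok = 1, True
        for a, b in zip(seq, seq[1:]):
            run = run + 1 if a is b else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return seq
    raise RuntimeError("side-sequence rejection sampling failed")  # pragma: no cover


def balanced_sides(
    n: int,
    rng: np.random.Generator,
    max_run: int = 3,
    extra: Side | None = None,
) -> list[Side]:
    """A random left/right sequence with balanced counts.

    Even ``n`` balances exactly; odd ``n`` gives the ``extra`` side (drawn
    from ``rng`` when None) one more appearance.  No more than ``max_run``
    consecutive equal sides.
    """
    half = n // 2
    base = [Side.LEFT] * half + [Side.RIGHT] * half
    if n % 2:
        if extra is None:
            extra = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        base.append(extra)
    return _permute_max_run(base, rng, max_run)


def build_schedule(
    condition: Condition | int | str,
    seed: int,
    *,
    max_same_side_run: int = 3,
) -> StimulusSchedule:
    """Build the deterministic stimulus schedule for one condition.

    Cycle structures:

    * 2D/3D: 1 s central fixation, then the target frame (red dot at
      +/-8 deg) opening a 1 s response window.
    * SO: 2.5 s fixation; 2.5 s combined egocentric/allocentric view (the
      circle target sits at +/-2 deg inside the small map); 2.5 s response
      frame with the egocentric targets at +/-8 deg.
    * VM: 2.5 s fixation; 2.5 s memorise frame (two distinct symbols at
      +/-2 deg); 2.5 s fixation; 2.5 s response frame in which one
      memorised symbol reappears at +/-8 deg.

    Recorded-trial sides are an exactly balanced seeded permutation.
    EO/EC have no visual schedule and are rejected.
    """
    if not isinstance(condition, Condition):
        condition = get_condition(condition)
    if condition.environment in (Environment.EO, Environment.EC):
        raise ValueError(
            f"condition {condition.name} has no visual stimulus schedule"
        )
    if condition.oculomotor_task not in (
        OculomotorTask.GAZE,
        OculomotorTask.PRO,
        OculomotorTask.ANTI,
    ):
        raise ValueError(f"no schedule for oculomotor task {condition.oculomotor_task}")

    cycle_dur, n_practice, n_recorded = _ENV_TIMING[condition.environment]

    rng = np.random.default_rng(seed)
    if condition.has_saccade_task:
        # The recorded block is balanced exactly when even; with the odd
        # 15-trial VM/SO block the seed decides its extra side and the
        # practice block takes the complementary extra, so left and right
        # targets appear an equal number of times over the whole schedule.
        if n_recorded % 2:
            extra = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
            recorded = balanced_sides(n_recorded, rng, max_same_side_run, extra)
            practice = balanced_sides(n_practice, rng, max_same_side_run,
                                      extra.mirrored())
        else:
            recorded = balanced_sides(n_recorded, rng, max_same_side_run)
            practice = balanced_sides(n_practice, rng, max_same_side_run)
        sides = practice + recorded
    else:
        sides = [Side.NONE] * (n_practice + n_recorded)

    events: list[StimulusEvent] = []
    env = condition.environment
    for i, side in enumerate(sides):
        t0 = i * cycle_dur
        practice = i < n_practice
        if env in (Environment.TWO_D, Environment.THREE_D):
            events.append(
                StimulusEvent(t0, FrameKind.CENTRAL_FIXATION, is_practice=practice,
                              trial_index=i, duration=_FRAME_2D3D)
            )
            if condition.has_saccade_task:
                events.append(
                    StimulusEvent(
                        t0 + _FRAME_2D3D, FrameKind.TARGET, side,
                        TARGET_ECCENTRICITY_DEG, is_practice=practice,
                        trial_index=i, duration=_FRAME_2D3D,
                    )
                )
            else:  # gaze task: fixation for the whole cycle
                events.append(
                    StimulusEvent(t0 + _FRAME_2D3D, FrameKind.CENTRAL_FIXATION,
                                  is_practice=practice, trial_index=i,
                                  duration=_FRAME_2D3D)
                )
        elif env is Environment.SO:
            events.append(
                StimulusEvent(t0, FrameKind.CENTRAL_FIXATION, is_practice=practice,
                              trial_index=i, duration=_FRAME_VMSO)
            )
            events.append(
                StimulusEvent(
                    t0 + _FRAME_VMSO, FrameKind.ALLOCENTRIC_VIEW, side,
                    INNER_ECCENTRICITY_DEG, Symbol.DISC,
                    is_practice=practice, trial_index=i, duration=_FRAME_VMSO,
                )
            )
            events.append(
                StimulusEvent(
                    t0 + 2 * _FRAME_VMSO, FrameKind.RESPONSE, side,
                    TARGET_ECCENTRICITY_DEG, Symbol.DISC,
                    is_practice=practice, trial_index=i, duration=_FRAME_VMSO,
                )
            )
        elif env is Environment.VM:
            pair_idx = rng.choice(len(VM_SYMBOLS), size=2, replace=False)
            left_sym, right_sym = VM_SYMBOLS[pair_idx[0]], VM_SYMBOLS[pair_idx[1]]
            cue = left_sym if side is Side.LEFT else right_sym
            events.append(
                StimulusEvent(t0, FrameKind.CENTRAL_FIXATION, is_practice=practice,
                              trial_index=i, duration=_FRAME_VMSO)
            )
            events.append(
                StimulusEvent(
                    t0 + _FRAME_VMSO, FrameKind.MEMORISE, Side.NONE,
                    INNER_ECCENTRICITY_DEG, cue, is_practice=practice,
                    trial_index=i, duration=_FRAME_VMSO,
                    symbols=(left_sym, right_sym),
                )
            )
            events.append(
                StimulusEvent(t0 + 2 * _FRAME_VMSO, FrameKind.CENTRAL_FIXATION,
                              is_practice=practice, trial_index=i,
                              duration=_FRAME_VMSO)
            )
            events.append(
                StimulusEvent(
                    t0 + 3 * _FRAME_VMSO, FrameKind.RESPONSE, side,
                    TARGET_ECCENTRICITY_DEG, cue, is_practice=practice,
                    trial_index=i, duration=_FRAME_VMSO,
                )
            )

    return StimulusSchedule(
        condition=condition,
        events=events,
        n_practice=n_practice,
        n_recorded=n_recorded,
        cycle_duration=cycle_dur,
        posture_recording_start=n_practice * cycle_dur,
        seed=seed,
    )


def expected_direction(condition: Condition, event: StimulusEvent) -> Side:
    """The correct saccade direction for a target/response event.

    Pro-saccade: toward the displayed stimulus side.  Anti-saccade: the
    mirrored side.  In VM the relevant side is where the memorised symbol
    reappears, in SO the side of the circle target inferred from the
    allocentric map; both are carried on the response event's ``side``, so
    the pro/anti rule applies uniformly.
    """
    if event.frame_kind not in (FrameKind.TARGET, FrameKind.RESPONSE):
        raise ValueError(f"{event.frame_kind} events carry no expected direction")
    task = condition.oculomotor_task
    if task is OculomotorTask.PRO:
        return event.side
    if task is OculomotorTask.ANTI:
        return event.side.mirrored()
    raise ValueError(f"task {task.value!r} has no expected direction")


# --- serialization ----------------------------------------------------------

_EVENT_FIELDS = ("t_onset", "frame_kind", "side", "eccentricity", "symbol",
                 "is_practice", "trial_index", "duration")


def _event_record(e: StimulusEvent) -> dict:
    d = {k: getattr(e, k) for k in _EVENT_FIELDS}
    d["frame_kind"] = e.frame_kind.value
    d["side"] = e.side.value
    d["symbol"] = e.symbol.value
    if e.symbols is not None:
        d["symbols"] = [s.value for s in e.symbols]
    return d


def schedule_to_json(schedule: StimulusSchedule, path) -> None:
    payload = {
        "condition": {
            "index": schedule.condition.index,
            "name": schedule.condition.name,
            "environment": schedule.condition.environment.value,
            "oculomotor_task": schedule.condition.oculomotor_task.value,
            "dual_task_flags": sorted(f.value for f in schedule.condition.dual_task_flags),
        },
        "n_practice": schedule.n_practice,
        "n_recorded": schedule.n_recorded,
        "cycle_duration": schedule.cycle_duration,
        "posture_recording_start": schedule.posture_recording_start,
        "seed": schedule.seed,
        "events": [_event_record(e) for e in schedule.events],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def schedule_from_json(path) -> StimulusSchedule:
    with open(path) as fh:
        payload = json.load(fh)
    condition = get_condition(payload["condition"]["index"])
    events = []
    for rec in payload["events"]:
        symbols = rec.get("symbols")
        events.append(
            StimulusEvent(
                t_onset=rec["t_onset"],
                frame_kind=FrameKind(rec["frame_kind"]),
                side=Side(rec["side"]),
                eccentricity=rec["eccentricity"],
                symbol=Symbol(rec["symbol"]),
                is_practice=rec["is_practice"],
                trial_index=rec["trial_index"],
                duration=rec["duration"],
                symbols=tuple(Symbol(s) for s in symbols) if symbols else None,
            )
        )
    return StimulusSchedule(
        condition=condition,
        events=events,
        n_practice=payload["n_practice"],
        n_recorded=payload["n_recorded"],
        cycle_duration=payload["cycle_duration"],
        posture_recording_start=payload["posture_recording_start"],
        seed=payload.get("seed", 0),
    )


def schedule_to_csv(schedule: StimulusSchedule, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EVENT_FIELDS)
        for e in schedule.events:
            rec = _event_record(e)
            writer.writerow([rec[k] for k in _EVENT_FIELDS])
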
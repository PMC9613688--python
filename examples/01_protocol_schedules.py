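"""Build the 11-condition battery and inspect one stimulus schedule.

The battery crosses four VR environments (2D, 3D, visuospatial memory,
spatial orientation) with pro-/anti-saccade tasks plus three control
conditions.  A schedule is a deterministic, seeded sequence of stimulus
frames; practice trials come first and posture recording starts when the
recorded trials begin.
"""

from collections import Counter

from oculosway import build_schedule, condition_table

for c in condition_table():
    flags = ",".join(sorted(f.value for f in c.dual_task_flags))
    print(f"#{c.index:>2} {c.name:<5} env={c.environment.value:<3} "
          f"task={c.oculomotor_task.value:<4} flags={{{flags}}}")

schedule = build_schedule("VM-P", seed=1)
print(f"\nVM-P schedule: {schedule.n_cycles} cycles x "
      f"{schedule.cycle_duration} s = {schedule.total_duration:.0f} s, "
      f"posture recording starts at {schedule.posture_recording_start:.0f} s")
sides = Counter(e.side.value for e in schedule.response_events(recorded_only=False))
print(f"target sides over all trials: {dict(sides)}  (balanced by design)")
print("first recorded cycle frames:")
for e in schedule.events:
    if e.trial_index == schedule.n_practice:
        print(f"  t={e.t_onset:6.1f}s {e.frame_kind.value:<16} side={e.side.value:<5} "
              f"ecc={e.eccentricity:.0f} deg symbol={e.symbol.value}")
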
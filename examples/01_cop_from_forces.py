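"""Derive a center-of-pressure path from raw force-plate channels.

Builds a tiny synthetic recording (constant 700 N vertical load with a
sinusoidal moment about the plate y-axis), derives the COP via the
moment-balance formula, and segments it into protocol trials.
"""
import numpy as np

import posturo as po

fs = 200.0
schedule = po.TrialSchedule(n_conditions=1)  # 3 trials x 20 s, 5-s breaks
n = round(schedule.total_duration * fs) + 1
t = np.arange(n) / fs

# 700 N load; my = -ap * fz puts a 5 mm-amplitude, 0.3 Hz AP oscillation
ap_true_mm = 5.0 * np.sin(2 * np.pi * 0.3 * t)
rec = po.ForcePlateRecording(
    time=t,
    fx=np.zeros(n), fy=np.zeros(n), fz=np.full(n, 700.0),
    mx=np.zeros(n), my=-(ap_true_mm / 1000.0) * 700.0, mz=np.zeros(n),
    sampling_rate=fs,
)

traj = po.compute_cop(rec)
print(f"recording: {rec.duration:.1f} s at {fs:.0f} Hz")
print(f"recovered AP amplitude: {np.max(np.abs(traj.ap)):.3f} mm "
      "(should equal the 5 mm we injected)")

trials = po.segment_trials(traj, schedule)
for trial in trials:
    print(f"  condition {trial.label[0]}, trial {trial.label[1]}: "
          f"{trial.n_samples} samples ({trial.duration:.3f} s span)")
print("Each 20-s trial holds exactly 4000 samples (half-open windows), "
      "ready for the measure battery.")
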
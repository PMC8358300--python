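"""Generate the visual-conflict surround motion profile.

The VR surround panels tilt sinusoidally in the anteroposterior direction
with a 20-degree maximum angle and a 15 degrees/s maximum angular
velocity, which together fix the oscillation frequency.
"""
import numpy as np

import posturo as po

profile = po.SurroundMotionProfile()  # A=20 deg, Vmax=15 deg/s
t, theta = po.surround_motion(profile)

peak_angle = np.max(np.abs(theta))
peak_velocity = np.max(np.abs(np.diff(theta))) * profile.sampling_rate
print(f"implied frequency: {profile.frequency_hz:.4f} Hz "
      "(= Vmax / (2*pi*A))")
print(f"peak angle:        {peak_angle:.2f} deg (target 20)")
print(f"peak velocity:     {peak_velocity:.2f} deg/s (target 15)")
print()
print("This is the panel-angle time series driving the visual-conflict")
print("conditions: slow enough to be trackable, fast enough to contradict")
print("the stationary somatosensory and vestibular input.")
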
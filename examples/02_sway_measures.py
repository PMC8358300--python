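"""Compute the seven stabilometric measures on one synthetic trial.

Generates a 20-s quiet-standing trial with the calibrated baseline
(firm surface, stable surround) parameters and prints the measure battery.
"""
import posturo as po

params = po.default_params()
trial = po.generate_trial(params, condition=1, seed=42)
battery = po.measure_battery(po.center_trajectory(trial))

print("Condition-1 trial (20 s at 200 Hz):")
print(f"  mean distance  AP {battery.mean_ap:6.2f} mm   "
      f"ML {battery.mean_ml:6.2f} mm")
print(f"  mean velocity  AP {battery.vel_ap:6.2f} mm/s "
      f"ML {battery.vel_ml:6.2f} mm/s")
print(f"  95% ellipse area  {battery.area95:7.2f} mm^2")
print(f"  mean frequency AP {battery.mf_ap:6.2f} Hz   "
      f"ML {battery.mf_ml:6.2f} Hz")
print()
print("Distances describe sway magnitude about the mean COP, velocities the")
print("path length per second, the ellipse area the region holding ~95% of")
print("COP points, and the mean frequency the equivalent-sinusoid rate")
print("Vel/(4*sqrt(2)*Mean) per direction.")
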
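"""Run the acoustic-emission feedback controller on a synthetic focus.

The pressure ramps from 0.2 MPa in 0.02 MPa steps, one step per second,
until the 1.5*f0 ultra-harmonic tone appears in the burst spectrum; it then
drops to 25% of the peak for the rest of the 120 s sonication.
"""

from fusbbb import EmissionModel, SonicationConfig, derate_pressure, run_controller

config = SonicationConfig()
model = EmissionModel(onset_pressure_uh=0.36, onset_pressure_sh=0.36, seed=7)

trace = run_controller(model, config)

print(f"detection at burst {trace.detection_burst} "
      f"(t = {trace.detection_burst / config.prf:.0f} s)")
print(f"peak pressure     {trace.peak_pressure:.2f} MPa (source)")
print(f"plateau pressure  {trace.plateau_pressure:.2f} MPa "
      f"= {100 * trace.plateau_pressure / trace.peak_pressure:.0f}% of peak")
print(f"derated peak      {derate_pressure(trace.peak_pressure, config):.3f} MPa in situ")
# The peak is the pressure at which nonlinear microbubble emissions first
# appeared at this focus; the 25% plateau sustains BBB opening below the
# threshold for inertial cavitation.
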
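"""Micro-PTV round trip: synthetic tracer movie -> flow rate.

Generates a 640 fps movie of ~20 fluorescent tracers advected by a
pulsatile pump flow in a 30 um channel, then runs the full pipeline
(detection, Hungarian linking, 3-frame gap closing, B-spline smoothing)
and compares the recovered peak flow rate with the generator's truth.
"""

import numpy as np

from optofluidics import ptv, pump, synth

system = pump.PumpSystem()
drive = pump.DriveWaveform(period=0.25, duty_cycle=0.1, peak_current=1e-4,
                           duration=1.0)
profile = pump.integrate_pump_ode(system, drive)
stack, truth_tracks, record = synth.gen_particle_stack(
    seed=1, flow_time=profile.time, flow_rate=profile.flow_rate,
    n_frames=400, n_tracers=20,
)
print(f"stack: {stack.shape[0]} frames of {stack.shape[1]}x{stack.shape[2]} px")

spec = ptv.ImagingSpec()
detections = ptv.detect_particles(stack, spec)
u_max = 2.1 * record["peak_flow_m3_s"] * 1e18 / 900.0 / spec.frame_rate
tracks = ptv.link_detections(detections, max_disp=1.5 * u_max)
tracks = ptv.close_gaps(tracks, max_gap=3)
tracks = ptv.smooth_tracks(tracks)
print(f"{len(detections)} detections -> {tracks.n_tracks} tracks")

series = ptv.flow_rate_series(tracks)
peak = float(np.nanmax(series["q_m3_s"]))
truth = record["peak_flow_m3_s"]
print(f"recovered peak flow: {peak * 1e12:.3f} nL/s")
print(f"true peak flow     : {truth * 1e12:.3f} nL/s "
      f"({100 * abs(peak - truth) / truth:.1f}% error)")
print("\nPer-frame velocities are fit to the analytic square-duct profile,")
print("so a handful of tracers per frame suffices to time-resolve the flow.")
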
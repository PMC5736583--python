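"""Track migrating cells and measure their clockwise heading bias.

Simulates amoeboid walkers with a +0.8°/min clockwise heading bias,
renders them as a DIC movie, converts to self-luminous intensity,
segments by watershed, links centroids with optical-flow assistance and
summarizes the per-track angular velocities.
"""

import numpy as np

from rtdic import (SynthSpec, chirality_stats, link_tracks, pyramid_flow,
                   rtdic_convert, segment_cells, walker_movie_2d)

spec = SynthSpec(shape=(360, 360), pitch=2.58, dt=30.0, n_frames=40,
                 n_walkers=25, walker_speed=10.0, angular_bias=0.8,
                 heading_noise=10.0, walker_sigma=5.0, seed=1)
movie, ground_truth = walker_movie_2d(spec, as_dic=True)
converted = rtdic_convert(movie, threshold_at_zero=True)

labels, detections = [], []
for frame in converted.data:
    lab, det = segment_cells(frame, smooth_sigma=1.5, h_frac=0.05,
                             pitch=spec.pitch)
    labels.append(lab)
    detections.append(det)

flows = [pyramid_flow(converted.data[k], converted.data[k + 1], levels=3,
                      n_iter=30, warps=1, tol=1e-4)[0]
         for k in range(converted.n_frames - 1)]
tracks = link_tracks(labels, detections, flows, pitch=spec.pitch,
                     dt=spec.dt)
per_track, summary = chirality_stats(tracks, min_step=0.5)

print(f"tracks: {summary['n_tracks']} "
      f"(excluded short: {summary['n_excluded']})")
print(f"mean angular velocity: "
      f"{summary['mean_angular_velocity']:+.2f} deg/min "
      f"(s.e.m. {summary['sem_angular_velocity']:.2f}; "
      f"simulated bias +{spec.angular_bias} deg/min)")
print(f"mean signed curvature: "
      f"{summary['mean_signed_curvature']:+.2f} rad/mm")
print("Positive values are clockwise on screen (y points down); a cell")
print("turning at +0.8 deg/min completes one revolution in ~7.5 h and")
print("traces a circle of radius speed/omega ~ 700 um.")
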
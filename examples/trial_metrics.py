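"""Per-trial precision metrics from a small hand-built trajectory."""

import numpy as np

from watermaze import metrics
from watermaze.dataio import Trajectory, TrialRecord

rec = TrialRecord(
    subject_id="S1", group="young", trial_index=1, phase="delayed_probe",
    block=5, target_id="T1", target_pos=(0.0, 2.0), start_id=1,
    start_pos=(0.0, 0.0), start_type="different",
    response_pos=(0.5, 2.0), response_time_ms=4000.0, total_time_ms=5000.0)

# an L-shaped walk: east 0.5 m, then north 2 m; yaw follows the motion
xy = [(0, 0), (0.25, 0), (0.5, 0), (0.5, 1.0), (0.5, 2.0)]
yaw = [270, 270, 270, 0, 0]  # east is 270 deg CCW-from-north
traj = Trajectory("S1:1", t=np.arange(5) * 1.0, xy=np.array(xy, float),
                  yaw=np.array(yaw, float))

m = metrics.compute_trial_metrics(traj, rec)
print(f"distance error : {m.distance_error:.3f} m   (response to target)")
print(f"total path     : {m.total_path:.3f} m   (sampled walk length)")
print(f"optimal path   : {m.optimal_path:.3f} m   (straight start->target)")
print(f"excess path    : {m.excess_path:.3f} m")
print(f"total rotation : {m.total_rotation:.1f} deg (unsigned yaw accumulation)")
print(f"excess rotation: {m.excess_rotation:.1f} deg (minus the initial turn)")
print("\nmedian containment radius of errors {1.0, 2.0, 3.0}:",
      metrics.median_containment_radius([1.0, 2.0, 3.0]), "m")
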
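"""Aromatic-gate state and phenyl-ring mobility on the heme plane."""

import numpy as np

from memtun import synthetic as syn
from memtun.gate import (covered_area, gate_open_fraction, gate_series,
                         heme_plane, project_to_plane, ring_center)
from memtun.structio import Trajectory

open_params = syn.ToyProteinParams(gate_centers={
    100: (10.0, 0.0, 30.0), 114: (10.0, 5.0, 30.0), 476: (10.0, -8.0, 30.0)})
closed_params = syn.ToyProteinParams()  # default d2 = 6 A

open_model = syn.build_toy_anchored_protein(open_params)
closed_model = syn.build_toy_anchored_protein(closed_params)

# alternate open/closed poses, then classify frame by frame
frames = np.array([open_model.xyz, closed_model.xyz] * 5)
traj = Trajectory(open_model, frames)
series = gate_series(traj)
print(series.head(4))
print(f"gate open fraction: {gate_open_fraction(traj):.0f}% "
      f"(open iff d2 = F100-F476 ring distance > 7 A)")

# ring mobility: project the F100 ring centre on the heme plane over a
# jittered trajectory and estimate the covered area
rng = np.random.default_rng(5)
jittered = Trajectory(open_model, open_model.xyz[None]
                      + rng.normal(0, 0.4, (2000, open_model.n_atoms, 3)))
plane = heme_plane(open_model)
cloud = np.array([
    project_to_plane(ring_center(jittered.frame(i), 100),
                     heme_plane(jittered.frame(i)))[0]
    for i in range(jittered.n_frames)])
area = covered_area(cloud, bin_width=0.2, n_discard_iters=3)
print(f"area covered by the F100 ring centre on the heme plane: "
      f"{area:.2f} A^2 (larger area = more mobile ring)")
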
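"""The internal aromatic gate: ring distances, open states, ring mobility.

Three phenylalanine side chains guard the route between the buried active
site and the access tunnels.  Their state is tracked by two ring-centre
distances, d1 (first↔second ring, default F100↔F114) and d2
(first↔third, default F100↔F476); the gate counts as open when d2
strictly exceeds 7 Å.

Ring mobility is quantified by projecting the ring centres onto the heme
plane over a trajectory and estimating the area the projections cover
with a binned min/max estimator: the x range is split into 0.2 Å bins,
and in each bin the extreme y values are discarded three times over
before the surviving y range contributes ``bin width × (max − min)`` —
a deliberately outlier-robust area estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import HEME_RING_NITROGENS, PHENYL_RING_ATOMS
from .geometry import DegenerateGeometryError
from .structio import SelectionError, StructureModel, Trajectory

OPEN_D2 = 7.0  # Å; strict lower bound on d2 for an open gate


@dataclass
class GateState:
    """Per-frame gate descriptor."""

    frame: int
    d1: float
    d2: float
    open: bool


def ring_center(frame: StructureModel, residue_seq: int,
                ring_atoms: tuple[str, ...] = PHENYL_RING_ATOMS) -> np.ndarray:
    """Centroid of the six aromatic carbons of a phenyl ring."""
    mask = (frame.residue_seq == residue_seq) & np.isin(frame.atom_name, ring_atoms)
    found = frame.atom_name[mask]
    missing = set(ring_atoms) - set(found.tolist())
    if missing:
        raise SelectionError(
            f"residue {residue_seq}: missing ring atoms {sorted(missing)}")
    return frame.xyz[mask].mean(axis=0)


def gate_state(frame: StructureModel, frame_index: int = 0,
               gate_residues: tuple[int, int, int] = (100, 114, 476),
               open_threshold: float = OPEN_D2) -> GateState:
    """d1, d2 and the open flag for one frame (open iff d2 > threshold)."""
    r0, r1, r2 = (ring_center(frame, rs) for rs in gate_residues)
    d1 = float(np.linalg.norm(r0 - r1))
    d2 = float(np.linalg.norm(r0 - r2))
    return GateState(frame=frame_index, d1=d1, d2=d2, open=d2 > open_threshold)


def gate_series(traj: Trajectory,
                gate_residues: tuple[int, int, int] = (100, 114, 476),
                open_threshold: float = OPEN_D2) -> pd.DataFrame:
    """Per-frame gate table: frame, d1, d2, open."""
    rows = []
    for i in range(traj.n_frames):
        st = gate_state(traj.frame(i), i, gate_residues, open_threshold)
        rows.append({"frame": st.frame, "d1": st.d1, "d2": st.d2,
                     "open": st.open})
    return pd.DataFrame(rows)


def gate_open_fraction(traj: Trajectory,
                       gate_residues: tuple[int, int, int] = (100, 114, 476),
                       open_threshold: float = OPEN_D2,
                       sample_interval_ps: float | None = None) -> float:
    """% of sampled frames in which the gate is open."""
    t = traj if sample_interval_ps is None else traj.sample_every(sample_interval_ps)
    if t.n_frames == 0:
        raise ValueError("no frames to sample")
    series = gate_series(t, gate_residues, open_threshold)
    return float(100.0 * series["open"].mean())


# ---------------------------------------------------------------------------
# heme-plane projection and covered-area estimator

@dataclass
class HemePlaneFrame:
    """Orthonormal in-plane basis and normal of the heme plane."""

    origin: np.ndarray    # ring-nitrogen centroid
    e1: np.ndarray        # along NA→NC
    e2: np.ndarray        # NB→ND component orthogonal to e1
    normal: np.ndarray


def heme_plane(frame: StructureModel) -> HemePlaneFrame:
    """Heme-plane frame from the four porphyrin ring nitrogens.

    The first in-plane axis follows NA→NC; the second is the component of
    NB→ND orthogonal to it; the normal is their cross product.
    """
    heme = frame.role == "heme"
    coords = {}
    for name in HEME_RING_NITROGENS:
        mask = heme & (frame.atom_name == name)
        if not mask.any():
            raise SelectionError(f"heme ring atom {name} not found")
        coords[name] = frame.xyz[mask][0]
    v1 = coords["NC"] - coords["NA"]
    v2 = coords["ND"] - coords["NB"]
    n1 = np.linalg.norm(v1)
    if n1 < 1e-9:
        raise DegenerateGeometryError("NA and NC coincide")
    e1 = v1 / n1
    v2p = v2 - (v2 @ e1) * e1
    n2 = np.linalg.norm(v2p)
    if n2 < 1e-9:
        raise DegenerateGeometryError("heme ring atoms are collinear")
    e2 = v2p / n2
    origin = np.mean([coords[n] for n in HEME_RING_NITROGENS], axis=0)
    return HemePlaneFrame(origin=origin, e1=e1, e2=e2, normal=np.cross(e1, e2))


def project_to_plane(points: np.ndarray, plane: HemePlaneFrame) -> np.ndarray:
    """In-plane (x, y) coordinates of points; normal component discarded."""
    rel = np.atleast_2d(np.asarray(points, float)) - plane.origin
    return np.column_stack([rel @ plane.e1, rel @ plane.e2])


def covered_area(points2d: np.ndarray, bin_width: float = 0.2,
                 n_discard_iters: int = 3) -> float:
    """Robust area (Ų) covered by a 2-D point cloud.

    The x range is split into bins of ``bin_width``; in each bin the
    current minimum-y and maximum-y points are discarded, repeated
    ``n_discard_iters`` times, and the surviving y range contributes
    ``bin_width × (max_y − min_y)``.  Bins left with fewer than two points
    contribute zero, so isolated outliers cannot inflate the area.
    """
    pts = np.atleast_2d(np.asarray(points2d, float))
    if pts.shape[0] == 0:
        raise ValueError("need at least one point")
    if pts.shape[0] == 1:
        return 0.0
    x, y = pts[:, 0], pts[:, 1]
    lo = np.floor(x.min() / bin_width) * bin_width
    nbins = max(1, int(np.ceil((x.max() - lo) / bin_width)))
    idx = np.minimum(((x - lo) / bin_width).astype(int), nbins - 1)
    area = 0.0
    for b in range(nbins):
        ys = np.sort(y[idx == b])
        ys = ys[n_discard_iters:len(ys) - n_discard_iters] \
            if len(ys) > 2 * n_discard_iters else ys[:0]
        if len(ys) >= 2:
            area += bin_width * float(ys[-1] - ys[0])
    return area


def ring_projection_areas(traj: Trajectory,
                          gate_residues: tuple[int, ...] = (100, 114, 476),
                          bin_width: float = 0.2,
                          n_discard_iters: int = 3) -> dict[int, float]:
    """Heme-plane covered area (Ų) of each gate ring centre over a trajectory.

    The heme plane is recomputed every frame, so the projection follows
    the heme through rigid motion of the protein.
    """
    clouds: dict[int, list] = {rs: [] for rs in gate_residues}
    for i in range(traj.n_frames):
        fr = traj.frame(i)
        plane = heme_plane(fr)
        for rs in gate_residues:
            clouds[rs].append(project_to_plane(ring_center(fr, rs), plane)[0])
    return {rs: covered_area(np.array(c), bin_width, n_discard_iters)
            for rs, c in clouds.items()}
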
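"""Superposition, residue-range RMSD series, and crystallographic B-factors.

RMSD series follow the standard trajectory protocol: each frame is rigidly
superposed onto the reference using one primary atom set (by default the
backbone of the globular domain), and the RMSD of every named set is then
reported without re-fitting, so loop motions are measured in the frame of
the superposed domain.  B-factors are defined as (8π²/3)·⟨|rᵢ − ⟨rᵢ⟩|²⟩
per atom, averaged over the atoms of each residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DegenerateGeometryError, kabsch, rmsd
from .structio import SelectionError, StructureModel, Trajectory, select


@dataclass
class SuperpositionResult:
    """Optimal rigid fit of a mobile frame onto a reference."""

    rotation: np.ndarray      # 3×3, det = +1
    translation: np.ndarray   # 3-vector
    fit_rmsd: float           # Å over the fitted atom set
    atom_indices: np.ndarray

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def superpose(mobile_xyz: np.ndarray, reference_xyz: np.ndarray,
              atom_indices: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (no reflection) on an atom set."""
    idx = np.asarray(atom_indices)
    R, t = kabsch(mobile_xyz[idx], reference_xyz[idx])
    fitted = mobile_xyz[idx] @ R.T + t
    return SuperpositionResult(rotation=R, translation=t,
                               fit_rmsd=rmsd(fitted, reference_xyz[idx]),
                               atom_indices=idx)


def rmsd_series(traj: Trajectory, reference_frame: int = 0,
                atom_sets: dict[str, str] | None = None,
                fit_set: str | None = None) -> pd.DataFrame:
    """Per-frame RMSD (Å) of named residue sets after one common fit.

    ``atom_sets`` maps set names to selection expressions (e.g.
    ``{"domain": "resid 47-492 and backbone", "BC": "resid 93-116 and
    backbone"}``).  Frames are superposed on ``fit_set`` (default: the
    first named set); every set's RMSD is then computed without
    re-fitting.
    """
    sets = atom_sets or {"domain": "resid 47-492 and backbone",
                         "BC": "resid 93-116 and backbone",
                         "FG": "resid 208-230 and backbone"}
    topo = traj.topology
    indices = {}
    for name, expr in sets.items():
        idx = select(topo, expr).indices
        if len(idx) == 0:
            raise SelectionError(f"set {name!r} ({expr!r}) matched no atoms")
        indices[name] = idx
    primary = fit_set or next(iter(sets))
    ref = traj.frames[reference_frame]

    rows = []
    for i in range(traj.n_frames):
        sup = superpose(traj.frames[i], ref, indices[primary])
        moved = sup.apply(traj.frames[i])
        row = {"frame": i}
        for name, idx in indices.items():
            row[name] = rmsd(moved[idx], ref[idx])
        rows.append(row)
    return pd.DataFrame(rows)


def bfactors(traj: Trajectory, selection: str = "heavy",
             per_residue: bool = True,
             presuperpose_on: str | None = None,
             reference_frame: int = 0) -> pd.DataFrame:
    """Crystallographic-style B-factors (Ų) from positional fluctuations.

    B = (8π²/3)·⟨|r − ⟨r⟩|²⟩ per atom; per-residue values are means over
    the selected atoms of the residue.  Frames are assumed already
    superposed; pass ``presuperpose_on`` (a selection expression) to fit
    every frame onto the reference first and remove global rigid motion.
    """
    if traj.n_frames < 2:
        raise ValueError("B-factors need at least 2 frames")
    topo = traj.topology
    idx = select(topo, selection).indices
    if len(idx) == 0:
        raise SelectionError(f"selection {selection!r} matched no atoms")

    frames = traj.frames
    if presuperpose_on is not None:
        fit_idx = select(topo, presuperpose_on).indices
        if len(fit_idx) < 3:
            raise DegenerateGeometryError("superposition set too small")
        ref = frames[reference_frame]
        frames = np.array([
            superpose(frames[i], ref, fit_idx).apply(frames[i])
            for i in range(traj.n_frames)])

    coords = frames[:, idx, :]
    mean = coords.mean(axis=0)
    msf = np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0)
    b_atom = (8.0 * np.pi ** 2 / 3.0) * msf

    df = pd.DataFrame({
        "residue_seq": topo.residue_seq[idx],
        "residue_name": topo.residue_name[idx],
        "atom_name": topo.atom_name[idx],
        "bfactor": b_atom,
    })
    if not per_residue:
        return df
    out = (df.groupby("residue_seq")
             .agg(residue_name=("residue_name", "first"),
                  bfactor=("bfactor", "mean"))
             .reset_index())
    return out
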
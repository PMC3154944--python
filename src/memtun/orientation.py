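"""Orientation descriptors of a membrane-anchored protein.

The orientation of the protein in the bilayer is described per frame by
three parameters:

* ``d`` — the z-projection of the separation between the protein and
  membrane centres of mass (signed; the convention here is that the
  cytosolic side of the bilayer is +z),
* ``alpha`` — the angle between the z axis and v1, the vector connecting
  the midpoints of the Cα atoms of two helical-turn windows in helix I
  (defaults 285–289 → 312–316),
* ``beta`` — the analogous angle for v2, connecting a helix C turn to a
  helix F turn (defaults 127–131 → 197–201).

Additional descriptors: the transmembrane-helix inclination (principal
axis of its Cα trace vs z), the heme tilt (heme-plane/membrane-plane
dihedral), and the height of the protein above the head-group plane.
Histogram utilities locate the predominant orientation and pick a
representative frame whose parameters all lie within a window of the
histogram peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (DegenerateGeometryError, angle_to_z, folded_tilt,
                       kabsch, principal_axis)
from .structio import SelectionError, StructureModel, Trajectory, select


@dataclass
class OrientationConfig:
    """Residue windows and selections defining the orientation vectors."""

    v1_window_a: tuple[int, int] = (285, 289)
    v1_window_b: tuple[int, int] = (312, 316)
    v2_window_a: tuple[int, int] = (127, 131)
    v2_window_b: tuple[int, int] = (197, 201)
    tm_helix: tuple[int, int] = (1, 22)
    protein_selection: str = "role protein or role heme"
    membrane_selection: str = "role lipid"

    def __post_init__(self):
        for a, b in ((self.v1_window_a, self.v1_window_b),
                     (self.v2_window_a, self.v2_window_b)):
            if a[0] > a[1] or b[0] > b[1]:
                raise ValueError("window ranges must be increasing")
            if not (a[1] < b[0] or b[1] < a[0]):
                raise ValueError("windows of one vector must be disjoint")


class IncompleteWindowError(SelectionError):
    """A residue window is missing Cα atoms."""


def _window_midpoint(model: StructureModel, window: tuple[int, int],
                     coords: np.ndarray | None = None) -> np.ndarray:
    lo, hi = window
    mask = ((model.residue_seq >= lo) & (model.residue_seq <= hi)
            & (model.atom_name == "CA"))
    expected = set(range(lo, hi + 1))
    found = set(model.residue_seq[mask].tolist())
    if found != expected:
        missing = sorted(expected - found)
        raise IncompleteWindowError(
            f"window {lo}-{hi} missing Cα for residues {missing}")
    xyz = coords if coords is not None else model.xyz
    return xyz[mask].mean(axis=0)


def compute_vectors(frame: StructureModel, config: OrientationConfig | None = None,
                    coords: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Orientation vectors v1 and v2 from the Cα window midpoints."""
    cfg = config or OrientationConfig()
    v1 = (_window_midpoint(frame, cfg.v1_window_b, coords)
          - _window_midpoint(frame, cfg.v1_window_a, coords))
    v2 = (_window_midpoint(frame, cfg.v2_window_b, coords)
          - _window_midpoint(frame, cfg.v2_window_a, coords))
    for v, nm in ((v1, "v1"), (v2, "v2")):
        if np.linalg.norm(v) < 1e-9:
            raise DegenerateGeometryError(f"{nm} has zero length")
    return v1, v2


def orientation_angles(v1: np.ndarray, v2: np.ndarray) -> tuple[float, float]:
    """Angles (degrees, [0, 180]) of v1 and v2 against the z axis."""
    return angle_to_z(v1), angle_to_z(v2)


def com_distance_z(frame: StructureModel,
                   protein_selection: str = "role protein or role heme",
                   membrane_selection: str = "role lipid",
                   euclidean: bool = False) -> float:
    """Signed z-projection of the protein–membrane COM separation (Å).

    With ``euclidean=True`` the full COM distance is returned instead of
    its z component.
    """
    masses = frame.masses()
    out = []
    for expr in (protein_selection, membrane_selection):
        idx = select(frame, expr).indices
        if len(idx) == 0:
            raise SelectionError(f"selection {expr!r} matched no atoms")
        out.append(np.average(frame.xyz[idx], axis=0, weights=masses[idx]))
    diff = out[0] - out[1]
    return float(np.linalg.norm(diff)) if euclidean else float(diff[2])


def helix_tilt(frame: StructureModel, tm_range: tuple[int, int] = (1, 22),
               atom_names: tuple[str, ...] = ("CA",)) -> float:
    """Inclination (deg, [0, 90]) of the TM helix best-fit axis to z."""
    mask = ((frame.residue_seq >= tm_range[0]) & (frame.residue_seq <= tm_range[1])
            & np.isin(frame.atom_name, atom_names))
    pts = frame.xyz[mask]
    if pts.shape[0] < 4:
        raise DegenerateGeometryError(
            f"need ≥ 4 backbone atoms in {tm_range}, found {pts.shape[0]}")
    return folded_tilt(principal_axis(pts))


def heme_tilt(frame: StructureModel) -> float:
    """Dihedral (deg, [0, 90]) between the heme plane and the membrane plane.

    The heme-plane normal is the cross product of the NA→NC and NB→ND
    vectors; the membrane plane is xy, so the tilt is the angle between
    that normal and z, folded into [0, 90].
    """
    coords = {}
    heme = frame.role == "heme"
    for name in ("NA", "NB", "NC", "ND"):
        mask = heme & (frame.atom_name == name)
        if not mask.any():
            raise SelectionError(f"heme ring atom {name} not found")
        coords[name] = frame.xyz[mask][0]
    n = np.cross(coords["NC"] - coords["NA"], coords["ND"] - coords["NB"])
    if np.linalg.norm(n) < 1e-9:
        raise DegenerateGeometryError("heme ring atoms are collinear")
    return folded_tilt(n)


def height_above_membrane(frame: StructureModel,
                          protein_selection: str = "role protein and heavy",
                          headgroup_selection: str = "role lipid and name P N4") -> float:
    """Max protein heavy-atom z minus the mean upper-leaflet head-group z."""
    prot = select(frame, protein_selection).indices
    heads = select(frame, headgroup_selection).indices
    if len(prot) == 0 or len(heads) == 0:
        raise SelectionError("empty protein or head-group selection")
    head_z = frame.xyz[heads][:, 2]
    upper = head_z[head_z > np.median(frame.xyz[select(frame, 'role lipid').indices][:, 2])]
    if len(upper) == 0:
        raise SelectionError("no upper-leaflet head-group atoms found")
    return float(frame.xyz[prot][:, 2].max() - upper.mean())


# ---------------------------------------------------------------------------
# per-trajectory records and histogram peak selection

def orientation_records(traj: Trajectory,
                        config: OrientationConfig | None = None,
                        include_extras: bool = False) -> pd.DataFrame:
    """Per-frame orientation parameters as a DataFrame.

    Columns: frame, d, alpha, beta (+ helix_tilt, heme_tilt, height when
    ``include_extras`` and the features are present).
    """
    cfg = config or OrientationConfig()
    topo = traj.topology
    masses = topo.masses()
    prot_idx = select(topo, cfg.protein_selection).indices
    mem_idx = select(topo, cfg.membrane_selection).indices
    if len(prot_idx) == 0 or len(mem_idx) == 0:
        raise SelectionError("protein or membrane selection matched no atoms")
    wp = masses[prot_idx] / masses[prot_idx].sum()
    wm = masses[mem_idx] / masses[mem_idx].sum()

    # validate windows once (raises IncompleteWindowError if any Cα missing),
    # then evaluate all frames vectorised
    compute_vectors(topo, cfg)

    def window_mask(window):
        lo, hi = window
        return ((topo.residue_seq >= lo) & (topo.residue_seq <= hi)
                & (topo.atom_name == "CA"))

    def midpoints(window):
        return traj.frames[:, window_mask(window), :].mean(axis=1)

    v1 = midpoints(cfg.v1_window_b) - midpoints(cfg.v1_window_a)
    v2 = midpoints(cfg.v2_window_b) - midpoints(cfg.v2_window_a)

    def z_angle(v):
        return np.degrees(np.arccos(np.clip(
            v[:, 2] / np.linalg.norm(v, axis=1), -1.0, 1.0)))

    d = traj.frames[:, prot_idx, 2] @ wp - traj.frames[:, mem_idx, 2] @ wm
    out = pd.DataFrame({"frame": np.arange(traj.n_frames), "d": d,
                        "alpha": z_angle(v1), "beta": z_angle(v2)})
    if include_extras:
        extras = {"helix_tilt": [], "heme_tilt": [], "height": []}
        for i in range(traj.n_frames):
            fr = topo.with_coords(traj.frames[i])
            extras["helix_tilt"].append(helix_tilt(fr, cfg.tm_helix))
            for key, fn in (("heme_tilt", heme_tilt),
                            ("height", height_above_membrane)):
                try:
                    extras[key].append(fn(fr))
                except SelectionError:
                    extras[key].append(np.nan)
        for key, vals in extras.items():
            out[key] = vals
    return out


class NoRepresentativeError(RuntimeError):
    """No frame lies within the peak windows for all three parameters."""

    def __init__(self, msg, best_frames=None):
        super().__init__(msg)
        self.best_frames = best_frames or {}


def histogram_peak(values: np.ndarray, bin_width: float,
                   smooth_bins: float = 4.0) -> float:
    """Centre of the peak bin of a 1-D histogram.

    When the bin width is much finer than the sample spread, the raw
    argmax bin is dominated by counting noise (neighbouring bins near a
    flat mode differ by far less than √N).  The peak is therefore located
    on a Gaussian-smoothed copy of the counts (kernel σ of ``smooth_bins``
    bins, a bandwidth still well below typical orientation spreads); the
    returned value is the centre of the winning bin of the stated width.
    ``smooth_bins=0`` gives the raw argmax.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("no values to histogram")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    nbins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(values, bins=nbins, range=(lo, lo + nbins * bin_width))
    if smooth_bins > 0 and nbins > 2:
        from scipy.ndimage import gaussian_filter1d
        counts = gaussian_filter1d(counts.astype(float), sigma=smooth_bins,
                                   mode="nearest")
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


@dataclass
class PeakSelection:
    frame: int
    peaks: dict
    mode: str


def histogram_peak_select(records: pd.DataFrame,
                          bins: tuple[float, float, float] = (0.5, 1.0, 1.0),
                          window_frac: float = 0.01,
                          mode: str = "multiplicative",
                          pick: str = "first") -> PeakSelection:
    """Representative frame whose (d, alpha, beta) all sit near the peaks.

    1-D histograms of d, alpha and beta are built with bin widths ``bins``;
    the frame returned is the earliest (``pick="first"``; ``"last"`` for
    the superposition-reference rule) whose three parameters each lie
    within ``window_frac`` of the respective peak-bin centre.  The window
    is multiplicative by default (±window_frac × peak value); an additive
    option (±window_frac in the parameter's own units) is available.
    """
    if len(records) == 0:
        raise ValueError("no orientation records")
    if mode not in ("multiplicative", "additive"):
        raise ValueError("mode must be 'multiplicative' or 'additive'")
    names = ("d", "alpha", "beta")
    peaks = {nm: histogram_peak(records[nm].to_numpy(), w)
             for nm, w in zip(names, bins)}
    ok = np.ones(len(records), dtype=bool)
    for nm in names:
        tol = abs(peaks[nm]) * window_frac if mode == "multiplicative" else window_frac
        ok &= np.abs(records[nm].to_numpy() - peaks[nm]) <= tol
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        best = {nm: int(records.iloc[(records[nm] - peaks[nm]).abs().argmin()]["frame"])
                for nm in names}
        raise NoRepresentativeError(
            f"no frame within the {window_frac:g} window of all peaks {peaks}",
            best_frames=best)
    chosen = idx[0] if pick == "first" else idx[-1]
    return PeakSelection(frame=int(records.iloc[chosen]["frame"]),
                         peaks=peaks, mode=mode)


def angle_variance_control(traj: Trajectory,
                           config: OrientationConfig | None = None,
                           backbone_selection: str = "backbone",
                           reference_window_frac: float = 0.03,
                           bins: tuple[float, float, float] = (0.5, 1.0, 1.0)
                           ) -> pd.DataFrame:
    """Angle deviations due to internal motion only, after superposition.

    A reference frame is chosen as the last frame whose (d, alpha, beta)
    all lie within ``reference_window_frac`` of the histogram peaks.  Every
    frame's backbone is rigidly superposed onto the reference, alpha and
    beta are recomputed from the superposed coordinates, and the reference
    values are subtracted.  A trajectory that differs from the reference
    only by rigid motions therefore yields identically zero deviations.
    """
    cfg = config or OrientationConfig()
    records = orientation_records(traj, cfg)
    sel = histogram_peak_select(records, bins=bins,
                                window_frac=reference_window_frac, pick="last")
    ref_i = sel.frame
    topo = traj.topology
    bb = select(topo, backbone_selection).indices
    if len(bb) < 3:
        raise SelectionError("backbone selection too small for superposition")
    ref_xyz = traj.frames[ref_i]
    v1r, v2r = compute_vectors(topo, cfg, coords=ref_xyz)
    a_ref, b_ref = orientation_angles(v1r, v2r)

    rows = []
    for i in range(traj.n_frames):
        xyz = traj.frames[i]
        R, t = kabsch(xyz[bb], ref_xyz[bb])
        moved = xyz @ R.T + t
        v1, v2 = compute_vectors(topo, cfg, coords=moved)
        a, b = orientation_angles(v1, v2)
        rows.append({"frame": i, "delta_alpha": a - a_ref, "delta_beta": b - b_ref})
    out = pd.DataFrame(rows)
    out.attrs["reference_frame"] = ref_i
    return out
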
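"""Tunnel detection from a buried cavity to the protein surface.

A clearance field is sampled on a regular grid: at each node, the largest
sphere centred there that touches no atom (distance to the nearest atom
centre minus that atom's van der Waals radius, clipped at zero).  Tunnels
are widest-bottleneck paths — paths from a buried start point to the grid
boundary that maximise the *minimum* clearance encountered — found by
best-first (Dijkstra-style max-min) search on the 26-connected grid.

Detected tunnel profiles are assigned to named entrances (the geometric
centre of the Cα atoms of defining residues), classified open when their
bottleneck radius strictly exceeds 1.2 Å (slightly below the 1.4 Å water
probe, compensating for grid-sampled radii reading low), and summarised
as per-label open fractions and opening/closing co-occurrence (phi
coefficient) matrices.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import SelectionError, StructureModel, Trajectory

OPEN_RADIUS = 1.2  # Å; strict lower bound for an open tunnel


class GeometryError(ValueError):
    """Raised for empty or unusable geometry."""


@dataclass
class ClearanceGrid:
    """Regular grid of probe-free radii (Å)."""

    origin: np.ndarray            # (3,) position of node (0, 0, 0)
    spacing: float
    values: np.ndarray            # (nx, ny, nz), clipped at 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def node_position(self, ijk) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=float) * self.spacing

    def nearest_node(self, point) -> tuple[int, int, int]:
        ijk = np.round((np.asarray(point, float) - self.origin) / self.spacing)
        ijk = np.clip(ijk, 0, np.array(self.shape) - 1).astype(int)
        return tuple(ijk)


def clearance_grid(model: StructureModel, spacing: float = 0.6,
                   padding: float = 2.0,
                   bounds: tuple | None = None) -> ClearanceGrid:
    """Sample the clearance field on a grid over the model's bounding box.

    Clearance at a node is ``min over atoms (|node − atom| − r_vdw)``,
    clipped at zero.  ``bounds`` may fix the box as (lower, upper) corners.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if model.n_atoms == 0:
        raise GeometryError("empty frame")
    if bounds is None:
        lo = model.xyz.min(axis=0) - padding
        hi = model.xyz.max(axis=0) + padding
    else:
        lo, hi = (np.asarray(b, float) for b in bounds)
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    nodes = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    radii = model.vdw_radii()
    clearance = np.full(len(nodes), np.inf)
    for r in np.unique(radii):
        tree = cKDTree(model.xyz[radii == r])
        dist = tree.query(nodes, k=1)[0]
        clearance = np.minimum(clearance, dist - r)
    values = np.clip(clearance, 0.0, None).reshape(tuple(shape))
    return ClearanceGrid(origin=np.asarray(lo, float), spacing=spacing,
                         values=values)


@dataclass
class TunnelProfile:
    """Ordered sphere centres and radii from the start point outward."""

    centers: np.ndarray           # (m, 3) Å
    radii: np.ndarray             # (m,)
    label: str | None = None

    @property
    def min_radius(self) -> float:
        return float(self.radii.min())

    @property
    def n_segments(self) -> int:
        return len(self.radii)


_NEIGHBOR_OFFSETS = np.array([(di, dj, dk)
                              for di in (-1, 0, 1)
                              for dj in (-1, 0, 1)
                              for dk in (-1, 0, 1)
                              if (di, dj, dk) != (0, 0, 0)])


def widest_path_field(grid: ClearanceGrid, start_ijk: tuple[int, int, int]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Best achievable bottleneck from the start to every grid node.

    Returns ``(bottleneck, predecessor)`` as flat arrays over the grid;
    unreachable nodes (or nodes with zero clearance) have bottleneck 0 and
    predecessor −1.  The search is best-first on the 26-connected grid,
    relaxing ``bottleneck(v) = max(bottleneck(v), min(bottleneck(u),
    clearance(v)))`` — Dijkstra with max-min instead of sum-min.
    """
    nx, ny, nz = grid.shape
    vals = grid.values.ravel()
    n = vals.size
    bott = np.zeros(n)
    pred = np.full(n, -1, dtype=np.int64)
    s = (start_ijk[0] * ny + start_ijk[1]) * nz + start_ijk[2]
    if vals[s] <= 0:
        raise GeometryError("start point has zero clearance")
    bott[s] = vals[s]
    heap = [(-bott[s], s)]
    flat_off = (_NEIGHBOR_OFFSETS[:, 0] * ny + _NEIGHBOR_OFFSETS[:, 1]) * nz \
        + _NEIGHBOR_OFFSETS[:, 2]
    yz = ny * nz
    while heap:
        nb, u = heapq.heappop(heap)
        nb = -nb
        if nb < bott[u] - 1e-12:
            continue
        ui, rem = divmod(u, yz)
        uj, uk = divmod(rem, nz)
        for (di, dj, dk), off in zip(_NEIGHBOR_OFFSETS, flat_off):
            vi, vj, vk = ui + di, uj + dj, uk + dk
            if not (0 <= vi < nx and 0 <= vj < ny and 0 <= vk < nz):
                continue
            v = u + off
            if vals[v] <= 0:
                continue
            w = nb if nb < vals[v] else vals[v]
            if w > bott[v]:
                bott[v] = w
                pred[v] = u
                heapq.heappush(heap, (-w, v))
    return bott, pred


def _boundary_flat_indices(shape) -> np.ndarray:
    nx, ny, nz = shape
    idx = np.arange(nx * ny * nz).reshape(shape)
    faces = [idx[0], idx[-1], idx[:, 0], idx[:, -1], idx[:, :, 0], idx[:, :, -1]]
    return np.unique(np.concatenate([f.ravel() for f in faces]))


def _resample_path(points: np.ndarray, radii: np.ndarray,
                   n_segments: int) -> tuple[np.ndarray, np.ndarray]:
    if len(points) <= 1:
        return points, radii
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return points[:1], radii[:1]
    t = np.linspace(0.0, s[-1], min(n_segments, max(len(points), 2)))
    out_pts = np.column_stack([np.interp(t, s, points[:, k]) for k in range(3)])
    out_r = np.interp(t, s, radii)
    return out_pts, out_r


def find_tunnels(grid: ClearanceGrid, start, n_tunnels: int = 10,
                 d_sep: float = 8.0, max_segments: int = 200
                 ) -> list[TunnelProfile]:
    """Widest-bottleneck paths from a buried start point to the surface.

    The ``n_tunnels`` best boundary exits with mutually distinct exit
    regions (exit points at least ``d_sep`` apart) are returned, each as a
    path resampled to at most ``max_segments`` equidistant segments with
    linearly interpolated clearance radii.  If no positive-clearance path
    reaches the boundary, the list is empty.
    """
    start_ijk = grid.nearest_node(start)
    bott, pred = widest_path_field(grid, start_ijk)
    boundary = _boundary_flat_indices(grid.shape)
    boundary = boundary[bott[boundary] > 0]
    if boundary.size == 0:
        return []
    order = boundary[np.argsort(-bott[boundary])]
    nx, ny, nz = grid.shape

    def flat_to_pos(f):
        i, rem = divmod(int(f), ny * nz)
        j, k = divmod(rem, nz)
        return grid.node_position((i, j, k))

    chosen = []
    exits = []
    for f in order:
        p = flat_to_pos(f)
        if any(np.linalg.norm(p - q) < d_sep for q in exits):
            continue
        exits.append(p)
        chosen.append(int(f))
        if len(chosen) >= n_tunnels:
            break

    vals = grid.values.ravel()
    profiles = []
    for f in chosen:
        path = [f]
        while pred[path[-1]] != -1:
            path.append(int(pred[path[-1]]))
        path.reverse()  # start first
        pts = np.array([flat_to_pos(x) for x in path])
        radii = vals[path]
        pts, radii = _resample_path(pts, radii, max_segments)
        profiles.append(TunnelProfile(centers=pts, radii=radii))
    return profiles


# ---------------------------------------------------------------------------
# entrances, assignment, open/closed statistics

TunnelEntranceSet = dict[str, tuple[int, ...]]
"""Mapping of tunnel label to the residues whose Cα centre defines its entrance."""

#: Entrance-defining residues for the two protein conformers studied
#: (helical FG loop vs extended FG loop).
ENTRANCES_HELICAL_FG: TunnelEntranceSet = {
    "2a": (69, 72, 101), "2b": (72, 74, 97, 99), "2c": (106, 108, 237, 288),
    "2ac": (101, 106, 221, 230), "2e": (98, 101, 106, 109),
    "2f": (37, 45, 218, 221), "S": (206, 300, 307, 476),
}
ENTRANCES_EXTENDED_FG: TunnelEntranceSet = {
    "2a": (72, 101, 220, 221), "2b": (72, 74, 97, 99), "2c": (106, 108, 237, 288),
    "2ac": (102, 106, 222, 230), "2e": (98, 101, 106, 109),
    "2f": (42, 47, 215, 211), "S": (206, 300, 307, 476),
}


def entrance_points(frame: StructureModel,
                    entrances: TunnelEntranceSet) -> dict[str, np.ndarray]:
    """Per-label geometric centre of the defining residues' Cα atoms."""
    out = {}
    for label, residues in entrances.items():
        pts = []
        for rs in residues:
            mask = (frame.residue_seq == rs) & (frame.atom_name == "CA") \
                & (frame.role == "protein")
            if not mask.any():
                raise SelectionError(
                    f"entrance {label}: residue {rs} has no Cα atom")
            pts.append(frame.xyz[mask][0])
        out[label] = np.mean(pts, axis=0)
    return out


def assign_tunnel(profile: TunnelProfile,
                  entrance_pts: dict[str, np.ndarray],
                  cutoff: float = 5.0) -> str | None:
    """Assign a profile to the unique entrance within the distance cutoff.

    A label is a candidate if at least one segment of the profile passes
    strictly closer than ``cutoff`` to its entrance point.  The profile is
    assigned only when exactly one label qualifies — if a second entrance
    is also within the cutoff of the path, the assignment is ambiguous and
    the profile stays unassigned.
    """
    if profile.n_segments == 0:
        return None
    candidates = []
    for label, pt in entrance_pts.items():
        dmin = np.linalg.norm(profile.centers - pt, axis=1).min()
        if dmin < cutoff:
            candidates.append(label)
    return candidates[0] if len(candidates) == 1 else None


def classify_open(profile: TunnelProfile,
                  threshold: float = OPEN_RADIUS) -> bool:
    """Open iff the bottleneck radius strictly exceeds the threshold."""
    if profile.n_segments == 0:
        raise ValueError("empty tunnel profile")
    return profile.min_radius > threshold


@dataclass
class TunnelTimeSeries:
    """Per-label bottleneck radii over frames (NaN where unassigned)."""

    min_radius: pd.DataFrame      # frames × labels, Å
    threshold: float = OPEN_RADIUS

    def open_flags(self) -> pd.DataFrame:
        """Boolean open table; frames with no assigned profile are closed."""
        return self.min_radius.gt(self.threshold).fillna(False)


def tunnel_time_series(traj: Trajectory, entrances: TunnelEntranceSet,
                       start, spacing: float = 0.6,
                       n_tunnels: int = 10, d_sep: float = 8.0,
                       sample_interval_ps: float | None = None,
                       threshold: float = OPEN_RADIUS) -> TunnelTimeSeries:
    """Detect, assign and profile tunnels for every sampled frame.

    ``start`` may be a fixed point or a callable mapping a frame's
    :class:`StructureModel` to the start point (e.g. the heme-proximal
    cavity centre).  Frames are sampled at ``sample_interval_ps`` when
    given (default: every stored frame).
    """
    t = traj if sample_interval_ps is None else traj.sample_every(sample_interval_ps)
    labels = list(entrances)
    table = np.full((t.n_frames, len(labels)), np.nan)
    for i in range(t.n_frames):
        fr = t.frame(i)
        pt = start(fr) if callable(start) else start
        grid = clearance_grid(fr, spacing=spacing)
        pts = entrance_points(fr, entrances)
        for prof in find_tunnels(grid, pt, n_tunnels=n_tunnels, d_sep=d_sep):
            label = assign_tunnel(prof, pts)
            if label is None:
                continue
            j = labels.index(label)
            r = prof.min_radius
            if np.isnan(table[i, j]) or r > table[i, j]:
                table[i, j] = r
    return TunnelTimeSeries(
        min_radius=pd.DataFrame(table, columns=labels), threshold=threshold)


def open_fraction(series: TunnelTimeSeries) -> pd.Series:
    """Per-label % of frames open (unassigned frames count as closed)."""
    flags = series.open_flags()
    if len(flags) == 0:
        raise ValueError("empty time series")
    return 100.0 * flags.mean(axis=0)


def tunnel_cooccurrence(series: TunnelTimeSeries) -> pd.DataFrame:
    """Pairwise phi coefficient between the open-flag time series.

    Pairs involving a constant series (always open or always closed) are
    undefined and reported as NaN.
    """
    flags = series.open_flags().to_numpy(dtype=float)
    if flags.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    labels = series.min_radius.columns
    n = len(labels)
    out = np.full((n, n), np.nan)
    std = flags.std(axis=0)
    for a in range(n):
        for b in range(n):
            if std[a] > 0 and std[b] > 0:
                out[a, b] = np.corrcoef(flags[:, a], flags[:, b])[0, 1]
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass
class EntranceStability:
    max_displacement: pd.Series      # per label, Å from trajectory mean
    min_pairwise_distance: float     # Å between mean entrance positions
    violation: bool


def entrance_stability_check(traj: Trajectory,
                             entrances: TunnelEntranceSet) -> EntranceStability:
    """Check that entrances move less than they are separated.

    Assignment by nearest entrance is only trustworthy if the maximum
    displacement of each entrance from its trajectory-mean position stays
    below the minimum distance between any two entrances; a violation is
    flagged otherwise.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    labels = list(entrances)
    pts = np.array([[entrance_points(traj.frame(i), entrances)[lb]
                     for lb in labels] for i in range(traj.n_frames)])
    means = pts.mean(axis=0)                      # (labels, 3)
    disp = np.linalg.norm(pts - means, axis=2).max(axis=0)
    dmin = np.inf
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            dmin = min(dmin, float(np.linalg.norm(means[a] - means[b])))
    return EntranceStability(
        max_displacement=pd.Series(disp, index=labels),
        min_pairwise_distance=float(dmin),
        violation=bool((disp >= dmin).any()))
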
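"""Synthetic membrane–protein systems with exact, recorded ground truth.

The analysis modules in this package operate on trajectories of a protein
anchored in a planar lipid bilayer.  Real inputs of that kind come from
molecular dynamics; for testing and calibration this module builds fully
synthetic surrogates in which every quantity of interest is imposed by
construction:

* a toy bilayer of pseudo-lipids with distinct head / middle / tail atoms
  in separate z bands,
* a toy anchored protein with an ideal transmembrane helix, labelled
  residue windows for the orientation vectors, three phenylalanine gate
  rings, a four-nitrogen heme proxy, and a hollow globular shell with an
  opening,
* rigid-body trajectories whose per-frame orientation parameters
  (d, alpha, beta) equal prescribed targets plus Gaussian noise, posed
  analytically so the recorded ground truth is exact,
* isotropic Gaussian-fluctuation trajectories for B-factor calibration,
* cavity fixtures with a known tunnel bottleneck radius.

Every generator is a pure function of its parameters and seed.  Ground
truth is stored in a sidecar table, never read by the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import rotation_about_axis, rotation_between_frames
from .structio import StructureModel, Trajectory, assign_roles


class ConstructionError(ValueError):
    """Raised when a synthetic system cannot be built as requested."""


# ---------------------------------------------------------------------------
# toy bilayer

# z offsets (Å) of the pseudo-lipid atoms in the upper leaflet, by part.
_LIPID_TEMPLATE = [
    ("P", "P", "head", 19.0),
    ("N4", "N", "head", 21.0),
    ("C21", "C", "middle", 13.0),
    ("O22", "O", "middle", 12.0),
    ("C31", "C", "tail", 8.0),
    ("C32", "C", "tail", 5.0),
    ("C33", "C", "tail", 2.0),
]


def build_toy_bilayer(nx: int, ny: int, spacing: float = 8.0,
                      seed: int = 0, jitter: float = 0.3) -> StructureModel:
    """Two leaflets of pseudo-lipids on a jittered rectangular grid.

    Each lipid carries seven atoms in three z bands (head around ±20 Å,
    middle around ±12.5 Å, tails toward the midplane at z = 0).  The box
    is ``(nx*spacing, ny*spacing)`` in-plane, so the constructed area per
    lipid is exactly ``spacing**2``.
    """
    if nx < 2 or ny < 2:
        raise ConstructionError("need at least a 2x2 lipid grid")
    if spacing <= 0:
        raise ConstructionError("spacing must be positive")
    rng = np.random.default_rng(seed)

    names, elements, res_seq, res_name, xyz = [], [], [], [], []
    resid = 0
    for leaflet_sign in (+1, -1):
        for ix in range(nx):
            for iy in range(ny):
                resid += 1
                x0 = (ix + 0.5) * spacing
                y0 = (iy + 0.5) * spacing
                dx, dy = rng.normal(0.0, jitter, size=2)
                for name, el, _part, z in _LIPID_TEMPLATE:
                    names.append(name)
                    elements.append(el)
                    res_seq.append(resid)
                    res_name.append("LIP")
                    p = np.array([x0 + dx, y0 + dy, leaflet_sign * z])
                    p += rng.normal(0.0, jitter, size=3)
                    xyz.append(p)

    n = len(names)
    res_name = np.array(res_name)
    return StructureModel(
        atom_id=np.arange(1, n + 1),
        atom_name=np.array(names),
        element=np.array(elements),
        residue_seq=np.array(res_seq),
        residue_name=res_name,
        chain=np.full(n, "M"),
        xyz=np.array(xyz),
        role=assign_roles(res_name),
        box=np.array([nx * spacing, ny * spacing, 80.0]),
    )


LIPID_PART_ATOMS: dict[str, tuple[str, ...]] = {
    "head": ("P", "N4"),
    "middle": ("C21", "O22"),
    "tail": ("C31", "C32", "C33"),
}
"""Atom names of the toy lipid grouped by part (head/middle/tail)."""


# ---------------------------------------------------------------------------
# toy anchored protein

@dataclass
class ToyProteinParams:
    """Feature placement for the toy anchored protein (author numbering)."""

    v1_window_a: tuple[int, int] = (285, 289)   # first helical turn, helix I
    v1_window_b: tuple[int, int] = (312, 316)   # last helical turn, helix I
    v2_window_a: tuple[int, int] = (127, 131)   # helix C turn
    v2_window_b: tuple[int, int] = (197, 201)   # helix F turn
    tm_helix: tuple[int, int] = (1, 22)
    linker: tuple[int, int] = (23, 37)
    gate_residues: tuple[int, int, int] = (100, 114, 476)
    heme_residue: int = 900
    # gate ring centres (Å); defaults give d1 = 5, d2 = 6 (gate closed)
    gate_centers: dict = field(default_factory=lambda: {
        100: (10.0, 0.0, 30.0),
        114: (10.0, 5.0, 30.0),
        476: (10.0, -6.0, 30.0),
    })
    heme_center: tuple[float, float, float] = (0.0, 0.0, 26.0)
    globule_center: tuple[float, float, float] = (0.0, 0.0, 35.0)
    globule_radius: float = 13.0
    channel_radius: float = 3.5     # opening of the hollow globule, along +x
    shell_spacing: float = 2.0
    shell_residue_start: int = 1000   # clear of every annotated residue id


def _ideal_helix_backbone(res_ids, origin, rise=1.5, radius=2.3,
                          twist_deg=100.0):
    """N/CA/C/O backbone of an ideal α-helix with axis along +z."""
    rows = []
    for k, rid in enumerate(res_ids):
        base = np.radians(twist_deg) * k
        zc = origin[2] + rise * k
        for name, dphi, dz, el in (("N", -0.55, -0.6, "N"), ("CA", 0.0, 0.0, "C"),
                                   ("C", 0.55, 0.6, "C"), ("O", 0.9, 0.8, "O")):
            x = origin[0] + radius * np.cos(base + dphi)
            y = origin[1] + radius * np.sin(base + dphi)
            rows.append((rid, name, el, np.array([x, y, zc + dz])))
    return rows


def _align_helix_axis_to_z(rows, res_ids):
    """Rotate helix atoms so the principal axis of their Cα trace is +z.

    A finite α-helix covering a non-integer number of turns has its
    best-fit line slightly off the geometric axis; this correction makes
    tilt ground truth exact for the analytic tilt estimator.
    """
    from .geometry import principal_axis
    xyz = np.array([r[3] for r in rows])
    ca = np.array([r[3] for r in rows if r[1] == "CA" and r[0] in res_ids])
    axis = principal_axis(ca)
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return rows
    R = rotation_about_axis(v, np.degrees(np.arcsin(np.clip(s, -1, 1))))
    center = ca.mean(axis=0)
    rotated = (xyz - center) @ R.T + center
    return [(rid, nm, el, x) for (rid, nm, el, _), x in zip(rows, rotated)]


def _hexagon(center, normal, radius=1.39):
    """Six points of a planar hexagon around ``center`` with plane ⟂ normal."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    pts = []
    for k in range(6):
        th = np.pi / 3.0 * k
        pts.append(np.asarray(center, float) + radius * (np.cos(th) * u + np.sin(th) * v))
    return pts


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def build_toy_anchored_protein(params: ToyProteinParams | None = None) -> StructureModel:
    """Rigid toy protein with annotated orientation/gate/heme/cavity features.

    The construction frame is canonical: v1 (between the two helix-I window
    midpoints) points along +z, v2 along +x, the transmembrane helix axis
    along z, the heme plane parallel to the xy plane.  Rigid-body posing of
    this model therefore maps construction angles to target angles exactly.
    """
    p = params or ToyProteinParams()
    rows = []  # (resid, resname, atom_name, element, xyz)

    # transmembrane helix, axis along z, spanning the bilayer interior
    tm_ids = list(range(p.tm_helix[0], p.tm_helix[1] + 1))
    tm_rows = _align_helix_axis_to_z(
        _ideal_helix_backbone(tm_ids, np.array([0.0, 0.0, -14.0])), set(tm_ids))
    for rid, name, el, x in tm_rows:
        rows.append((rid, "LEU", name, el, x))
    tm_top_z = -14.0 + 1.5 * (len(tm_ids) - 1)

    # linker: extended strand continuing upward, offset in y so it threads
    # the globule's bottom opening without touching the heme; proper
    # backbone so its dihedrals can be rotated downstream
    linker_ids = list(range(p.linker[0], p.linker[1] + 1))
    ly = 3.0
    for k, rid in enumerate(linker_ids):
        z = tm_top_z + 1.8 + 1.6 * k
        zig = 0.6 if k % 2 else -0.6
        rows.append((rid, "GLY", "N", "N", np.array([zig, ly - 0.4, z - 0.5])))
        rows.append((rid, "GLY", "CA", "C", np.array([zig, ly + 0.4, z])))
        rows.append((rid, "GLY", "C", "C", np.array([-zig * 0.3, ly + 0.2, z + 0.55])))
        rows.append((rid, "GLY", "O", "O", np.array([-zig * 0.3, ly + 1.3, z + 0.75])))

    gc = np.asarray(p.globule_center, float)

    # orientation windows: five Cα per window, symmetric about the window
    # midpoint so the midpoint is exact by construction
    def window(res_range, center, perp):
        c = np.asarray(center, float)
        perp = np.asarray(perp, float)
        out = []
        offsets = (-2.0, -1.0, 0.0, 1.0, 2.0)
        for rid, off in zip(range(res_range[0], res_range[1] + 1), offsets):
            out.append((rid, "ALA", "CA", "C", c + off * perp))
        return out

    half_v1 = 7.0
    rows += window(p.v1_window_a, gc + [0, 0, -half_v1], [0, 1, 0])
    rows += window(p.v1_window_b, gc + [0, 0, +half_v1], [0, 1, 0])
    rows += window(p.v2_window_a, gc + [-half_v1, 0, 0], [0, 1, 0])
    rows += window(p.v2_window_b, gc + [+half_v1, 0, 0], [0, 1, 0])

    # gate phenylalanines: CA + planar 6-carbon ring at the given centres
    ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    for rid in p.gate_residues:
        center = np.asarray(p.gate_centers[rid], float)
        rows.append((rid, "PHE", "CA", "C", center + [0.0, 0.0, 2.4]))
        for name, pt in zip(ring_names, _hexagon(center, [0.3, 0.2, 1.0])):
            rows.append((rid, "PHE", name, "C", pt))

    # heme proxy: four ring nitrogens in a plane parallel to xy, plus iron
    hc = np.asarray(p.heme_center, float)
    rows.append((p.heme_residue, "HEM", "FE", "FE", hc))
    rows.append((p.heme_residue, "HEM", "NA", "N", hc + [2.0, 0.0, 0.0]))
    rows.append((p.heme_residue, "HEM", "NB", "N", hc + [0.0, 2.0, 0.0]))
    rows.append((p.heme_residue, "HEM", "NC", "N", hc + [-2.0, 0.0, 0.0]))
    rows.append((p.heme_residue, "HEM", "ND", "N", hc + [0.0, -2.0, 0.0]))

    # hollow globular shell with an opening along +x: internal void
    # reachable from outside
    n_shell = int(np.ceil(4.0 * np.pi * p.globule_radius ** 2
                          / p.shell_spacing ** 2))
    pts = gc + p.globule_radius * _fibonacci_sphere(n_shell)
    rel = pts - gc
    axis_dist = np.sqrt(rel[:, 1] ** 2 + rel[:, 2] ** 2)
    keep = ~((rel[:, 0] > 0) & (axis_dist < p.channel_radius + 2.2))
    # bottom opening for the linker strand entering from the membrane
    bottom_dist = np.sqrt(rel[:, 0] ** 2 + (rel[:, 1] - ly) ** 2)
    keep &= ~((rel[:, 2] < -8.0) & (bottom_dist < 3.0))
    rid = p.shell_residue_start
    for pt in pts[keep]:
        rows.append((rid, "GLY", "CA", "C", pt))
        rid += 1

    res_seq = np.array([r[0] for r in rows])
    res_name = np.array([r[1] for r in rows])
    names = np.array([r[2] for r in rows])
    elements = np.array([r[3] for r in rows])
    xyz = np.array([r[4] for r in rows])

    # overlapping feature placements are construction errors
    from scipy.spatial import cKDTree
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=0.5)
    if pairs:
        raise ConstructionError(
            f"{len(pairs)} atom pairs closer than 0.5 Å; feature placements overlap")

    n = len(rows)
    return StructureModel(
        atom_id=np.arange(1, n + 1),
        atom_name=names,
        element=elements,
        residue_seq=res_seq,
        residue_name=res_name,
        chain=np.full(n, "A"),
        xyz=xyz,
        role=assign_roles(res_name),
    )


def combine(*models: StructureModel, box=None) -> StructureModel:
    """Concatenate models into one system with fresh atom ids."""
    n = sum(m.n_atoms for m in models)
    if box is None:
        for m in models:
            if m.box is not None:
                box = m.box
                break
    return StructureModel(
        atom_id=np.arange(1, n + 1),
        atom_name=np.concatenate([m.atom_name for m in models]),
        element=np.concatenate([m.element for m in models]),
        residue_seq=np.concatenate([m.residue_seq for m in models]),
        residue_name=np.concatenate([m.residue_name for m in models]),
        chain=np.concatenate([m.chain for m in models]),
        xyz=np.vstack([m.xyz for m in models]),
        role=np.concatenate([m.role for m in models]),
        box=box,
    )


# ---------------------------------------------------------------------------
# rigid-body trajectories with exact orientation ground truth

@dataclass
class OrientationSchedule:
    """Target orientation parameters and per-parameter Gaussian noise."""

    d: float = 39.5          # COM z-separation, Å
    alpha: float = 100.0     # v1–z angle, degrees
    beta: float = 123.0      # v2–z angle, degrees
    sigma_d: float = 0.0
    sigma_alpha: float = 0.0
    sigma_beta: float = 0.0


@dataclass
class GroundTruth:
    """Per-frame true orientation parameters recorded by the generator."""

    d: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    helix_tilt: np.ndarray
    clash_flag: np.ndarray
    sigma: dict
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.d)),
            "d": self.d, "alpha": self.alpha, "beta": self.beta,
            "helix_tilt": self.helix_tilt, "clash_flag": self.clash_flag,
        })

    def write(self, path) -> None:
        """Write the sidecar ground-truth table (TSV)."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _target_direction_pair(alpha_deg: float, beta_deg: float):
    """Unit vectors a, b with a·z = cos α, b·z = cos β, a·b = 0."""
    ca, cb = np.cos(np.radians(alpha_deg)), np.cos(np.radians(beta_deg))
    sa = np.sin(np.radians(alpha_deg))
    if abs(sa) < 1e-9:
        # v1 along ±z: any horizontal b with b·z = cb requires cb = 0
        if abs(cb) > 1e-9:
            raise ConstructionError("alpha ≈ 0/180 requires beta = 90")
        return np.array([0.0, 0.0, np.sign(ca) or 1.0]), np.array([1.0, 0.0, 0.0])
    a = np.array([sa, 0.0, ca])
    bx = -ca * cb / sa
    rest = 1.0 - bx * bx - cb * cb
    if rest < -1e-9:
        raise ConstructionError(
            f"no orthogonal pair realises alpha={alpha_deg}, beta={beta_deg}")
    by = np.sqrt(max(rest, 0.0))
    b = np.array([bx, by, cb])
    return a, b


def _window_midpoint(model, lo, hi):
    mask = ((model.residue_seq >= lo) & (model.residue_seq <= hi)
            & (model.atom_name == "CA"))
    return model.xyz[mask].mean(axis=0)


def generate_rigid_body_trajectory(
        system: StructureModel,
        schedule: OrientationSchedule,
        nframes: int,
        seed: int = 0,
        params: ToyProteinParams | None = None,
        clash_tolerance: float = 5.0,
) -> tuple[Trajectory, GroundTruth]:
    """Pose the protein rigidly each frame to exact noisy orientation targets.

    ``system`` must combine the toy protein with a bilayer.  Per frame the
    targets (d, alpha, beta) are perturbed with independent Gaussian noise,
    and the protein (with heme) is rotated/translated so the analytically
    computed orientation parameters match the noisy targets exactly; the
    membrane stays fixed.  Frames where protein atoms dip more than
    ``clash_tolerance`` below the bilayer midplane are flagged, not dropped.
    """
    p = params or ToyProteinParams()
    rng = np.random.default_rng(seed)
    prot_mask = np.isin(system.role, ["protein", "heme"])
    mem_mask = system.role == "lipid"
    if not prot_mask.any() or not mem_mask.any():
        raise ConstructionError("system must contain both protein and lipids")

    masses = system.masses()
    prot = system.subset(prot_mask)
    com_p = np.average(system.xyz[prot_mask], axis=0, weights=masses[prot_mask])
    com_m = np.average(system.xyz[mem_mask], axis=0, weights=masses[mem_mask])
    mem_top = system.xyz[mem_mask][:, 2].min()  # midplane proxy below

    # construction-frame orientation vectors
    u1 = _window_midpoint(prot, *p.v1_window_b) - _window_midpoint(prot, *p.v1_window_a)
    u2 = _window_midpoint(prot, *p.v2_window_b) - _window_midpoint(prot, *p.v2_window_a)
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)

    tm_mask = ((prot.residue_seq >= p.tm_helix[0])
               & (prot.residue_seq <= p.tm_helix[1]) & (prot.atom_name == "CA"))
    from .geometry import principal_axis
    helix_axis0 = principal_axis(prot.xyz[tm_mask])

    frames = np.repeat(system.xyz[None, :, :], nframes, axis=0)
    d_true = np.empty(nframes)
    a_true = np.empty(nframes)
    b_true = np.empty(nframes)

    tilt_true = np.empty(nframes)
    clash = np.zeros(nframes, dtype=bool)
    rel = system.xyz[prot_mask] - com_p
    midplane_z = com_m[2]
    for i in range(nframes):
        d_true[i] = schedule.d + (rng.normal(0.0, schedule.sigma_d)
                                  if schedule.sigma_d > 0 else 0.0)
        # draw the angle pair jointly until it is realisable by two
        # orthogonal vectors (cos²α + cos²β ≤ 1); extreme-tail combinations
        # are geometrically impossible for a rigid body and are redrawn
        for _ in range(1000):
            a_true[i] = schedule.alpha + (rng.normal(0.0, schedule.sigma_alpha)
                                          if schedule.sigma_alpha > 0 else 0.0)
            b_true[i] = schedule.beta + (rng.normal(0.0, schedule.sigma_beta)
                                         if schedule.sigma_beta > 0 else 0.0)
            try:
                a, b = _target_direction_pair(a_true[i], b_true[i])
                break
            except ConstructionError:
                continue
        else:
            raise ConstructionError(
                f"cannot realise angles near alpha={schedule.alpha}, "
                f"beta={schedule.beta}")
        R = rotation_between_frames(u1, u2, a, b)
        Rz = rotation_about_axis([0, 0, 1], rng.uniform(0.0, 360.0))
        R = Rz @ R
        target_com = np.array([com_m[0], com_m[1], com_m[2] + d_true[i]])
        posed = rel @ R.T + target_com
        frames[i, prot_mask] = posed
        ax = R @ helix_axis0
        t = np.degrees(np.arccos(np.clip(abs(ax[2]), -1.0, 1.0)))
        tilt_true[i] = t
        if posed[:, 2].min() < midplane_z - clash_tolerance:
            clash[i] = True

    truth = GroundTruth(
        d=d_true, alpha=a_true, beta=b_true, helix_tilt=tilt_true,
        clash_flag=clash,
        sigma={"d": schedule.sigma_d, "alpha": schedule.sigma_alpha,
               "beta": schedule.sigma_beta},
        seed=seed,
    )
    return Trajectory(system, frames), truth


def generate_helix_tilt_trajectory(
        mean_tilt: float = 12.0, sigma: float = 6.0,
        nframes: int = 1000, seed: int = 0) -> tuple[Trajectory, np.ndarray]:
    """Ideal-helix poses with true inclinations N(mean, sigma) folded to [0, 90].

    Returns the trajectory of the helix and the per-frame true tilt (deg).
    The tilt is imposed by rotating the canonical z-axis helix about a
    uniformly random in-plane axis.
    """
    rng = np.random.default_rng(seed)
    ids = list(range(1, 23))
    rows = _align_helix_axis_to_z(
        _ideal_helix_backbone(ids, np.array([0.0, 0.0, -15.0])), set(ids))
    names = np.array([r[1] for r in rows])
    elements = np.array([r[2] for r in rows])
    xyz0 = np.array([r[3] for r in rows])
    res_seq = np.array([r[0] for r in rows])
    res_name = np.full(len(rows), "LEU")
    helix = StructureModel(
        atom_id=np.arange(1, len(rows) + 1), atom_name=names, element=elements,
        residue_seq=res_seq, residue_name=res_name,
        chain=np.full(len(rows), "A"), xyz=xyz0,
        role=assign_roles(res_name),
    )
    tilts = np.abs(rng.normal(mean_tilt, sigma, nframes))
    tilts = np.where(tilts > 90.0, 180.0 - tilts, tilts)  # fold into [0, 90]
    center = xyz0.mean(axis=0)
    frames = np.empty((nframes, len(rows), 3))
    for i in range(nframes):
        phi = rng.uniform(0.0, 360.0)
        axis = rotation_about_axis([0, 0, 1], phi) @ np.array([1.0, 0.0, 0.0])
        R = rotation_about_axis(axis, tilts[i])
        frames[i] = (xyz0 - center) @ R.T + center
    return Trajectory(helix, frames), tilts


def generate_gaussian_fluctuation_trajectory(
        model: StructureModel, sigma: float, nframes: int,
        seed: int = 0) -> Trajectory:
    """Displace every atom i.i.d. isotropic Gaussian per frame (σ per axis)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(nframes, model.n_atoms, 3)) \
        if sigma > 0 else np.zeros((nframes, model.n_atoms, 3))
    return Trajectory(model, model.xyz[None, :, :] + noise)


# ---------------------------------------------------------------------------
# cavity fixture for tunnel detection

@dataclass
class CavityFixture:
    """Hollow shell with known channels, for oracle tests of tunnel finding."""

    model: StructureModel
    start_point: np.ndarray
    tunnels: list  # (label, entrance xyz, true bottleneck radius Å)


def build_cavity_fixture(bottleneck_radius: float = 2.0,
                         blocked: bool = False,
                         second_radius: float | None = None,
                         shell_radius: float = 9.0,
                         atom_vdw_element: str = "C") -> CavityFixture:
    """Spherical atom shell around a chamber, with cylindrical channel(s).

    One channel runs along +x with the requested clearance radius; an
    optional second channel of a different radius runs along −x.  With
    ``blocked=True`` the +x channel is filled and no tunnels are declared.
    Shell atoms are carbons (vdW 1.70 Å); channel walls are rings of atoms
    whose axis distance equals ``bottleneck_radius + r_vdw``, so the true
    maximal free-probe radius through the channel equals the request.
    """
    from .constants import vdw_radius
    r_vdw = vdw_radius(atom_vdw_element)
    if bottleneck_radius <= 0:
        raise ConstructionError("bottleneck radius must be positive")
    if bottleneck_radius + r_vdw > shell_radius - 2.0:
        raise ConstructionError("channel radius too large for the shell")

    channels = [(np.array([1.0, 0.0, 0.0]), bottleneck_radius, "T1")]
    if second_radius is not None:
        if second_radius + r_vdw > shell_radius - 2.0:
            raise ConstructionError("second channel radius too large for the shell")
        channels.append((np.array([-1.0, 0.0, 0.0]), second_radius, "T2"))

    spacing = 1.2
    n_shell = int(np.ceil(4.0 * np.pi * shell_radius ** 2 / spacing ** 2))
    pts = shell_radius * _fibonacci_sphere(n_shell)

    keep = np.ones(len(pts), dtype=bool)
    for axis, radius, _ in channels:
        along = pts @ axis
        perp = np.linalg.norm(pts - np.outer(along, axis), axis=1)
        keep &= ~((along > 0) & (perp < radius + r_vdw + 0.8))
    coords = [pts[keep]]

    x_end = shell_radius + 5.0
    for axis, radius, _ in channels:
        wall = radius + r_vdw
        xs = np.arange(4.0, x_end + 1e-9, spacing)
        n_ring = max(8, int(np.ceil(2.0 * np.pi * wall / spacing)))
        th = np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False)
        # orthonormal frame around the channel axis (axes are ±x here)
        u = np.array([0.0, 1.0, 0.0])
        v = np.cross(axis, u)
        rings = []
        for j, x in enumerate(xs):
            off = (np.pi / n_ring) * (j % 2)  # stagger to close diagonal gaps
            ring = (x * axis[None, :]
                    + wall * np.outer(np.cos(th + off), u)
                    + wall * np.outer(np.sin(th + off), v))
            rings.append(ring)
        coords.append(np.vstack(rings))

    if blocked:
        axis, radius, _ = channels[0]
        plug = []
        for x in np.arange(6.0, shell_radius + 2.0, 1.0):
            plug.append(x * axis)
            for rho in np.arange(1.0, radius + r_vdw, 1.0):
                thp = np.linspace(0, 2 * np.pi, 8, endpoint=False)
                u = np.array([0.0, 1.0, 0.0])
                v = np.cross(axis, u)
                plug.append(x * axis + rho * (np.outer(np.cos(thp), u)
                                              + np.outer(np.sin(thp), v)))
        plug = [np.atleast_2d(q) for q in plug]
        coords.append(np.vstack(plug))

    xyz = np.vstack(coords)
    n = len(xyz)
    res_name = np.full(n, "CAV")
    model = StructureModel(
        atom_id=np.arange(1, n + 1),
        atom_name=np.full(n, "C"),
        element=np.full(n, atom_vdw_element),
        residue_seq=np.arange(1, n + 1),
        residue_name=res_name,
        chain=np.full(n, "X"),
        xyz=xyz,
        role=np.full(n, "other"),
    )
    declared = []
    if not blocked:
        for axis, radius, label in channels:
            declared.append((label, x_end * axis, radius))
    return CavityFixture(model=model, start_point=np.zeros(3), tunnels=declared)
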
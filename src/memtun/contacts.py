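"""Protein–bilayer contact analysis and membrane-region classification.

Residues are located relative to the bilayer in one of three z slabs:
``M`` (the lipid-tail interior), ``HG`` (the head-group region, a slab of
configurable half-width around the mean head-group z of each leaflet) and
``C`` (the cytosol, outside the head groups on the protein side — and, by
extension, anywhere outside the membrane).  Contacts are counted between
protein residues (grouped into six chemical categories) and the three
parts of the lipids (head, middle, tail): a residue contacts a lipid part
in a frame if any of its heavy atoms lies strictly closer than the cutoff
(default 4 Å) to any heavy atom of that part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import RESIDUE_CATEGORIES, residue_category
from .structio import SelectionError, StructureModel, Trajectory
from .synthetic import LIPID_PART_ATOMS

LIPID_PARTS = ("head", "middle", "tail")


class GeometryError(ValueError):
    """Raised when membrane geometry cannot be established."""


@dataclass
class MembraneFrameGeometry:
    """Per-frame z geometry of the bilayer."""

    upper_head_z: float
    lower_head_z: float
    hg_halfwidth: float
    midplane_z: float
    leaflet: dict            # lipid residue_seq -> "upper" | "lower"
    protein_side: int = +1   # +1: protein (cytosol) above the membrane

    @property
    def tail_interval(self) -> tuple[float, float]:
        """z interval of the lipid-tail (M) region."""
        return (self.lower_head_z + self.hg_halfwidth,
                self.upper_head_z - self.hg_halfwidth)


def frame_geometry(frame: StructureModel,
                   hg_halfwidth: float = 4.0,
                   head_atoms: tuple[str, ...] | None = None) -> MembraneFrameGeometry:
    """Leaflet assignment and region boundaries for one frame.

    Lipids are split into leaflets by their centroid z relative to the
    bilayer midplane (the mean lipid z); the head-group plane of each
    leaflet is the mean z of its head atoms, and the HG region extends
    ``hg_halfwidth`` on either side of that plane.
    """
    lip = frame.role == "lipid"
    if not lip.any():
        raise GeometryError("no lipid atoms in frame")
    heads = head_atoms or LIPID_PART_ATOMS["head"]
    mid_z = float(frame.xyz[lip][:, 2].mean())

    leaflet = {}
    upper_heads, lower_heads = [], []
    for rs in np.unique(frame.residue_seq[lip]):
        rmask = lip & (frame.residue_seq == rs)
        side = "upper" if frame.xyz[rmask][:, 2].mean() >= mid_z else "lower"
        leaflet[int(rs)] = side
        hmask = rmask & np.isin(frame.atom_name, heads)
        if hmask.any():
            (upper_heads if side == "upper" else lower_heads).append(
                frame.xyz[hmask][:, 2])
    if not upper_heads or not lower_heads:
        raise GeometryError("bilayer must have lipids in both leaflets")
    upper_z = float(np.concatenate(upper_heads).mean())
    lower_z = float(np.concatenate(lower_heads).mean())
    if upper_z - lower_z < 2.0 * hg_halfwidth:
        raise GeometryError(
            "head-group planes are not separated; input is not a bilayer")

    prot = frame.role == "protein"
    side = +1
    if prot.any():
        side = +1 if frame.xyz[prot][:, 2].mean() >= mid_z else -1
    return MembraneFrameGeometry(
        upper_head_z=upper_z, lower_head_z=lower_z,
        hg_halfwidth=hg_halfwidth, midplane_z=mid_z,
        leaflet=leaflet, protein_side=side)


def residue_region(frame: StructureModel, residue_seq: int,
                   geometry: MembraneFrameGeometry) -> str:
    """Region (``M``/``HG``/``C``) of a residue's heavy-atom centroid."""
    mask = (frame.residue_seq == residue_seq) & (frame.role != "lipid") \
        & frame.is_heavy()
    if not mask.any():
        mask = (frame.residue_seq == residue_seq) & (frame.role != "lipid")
    if not mask.any():
        raise SelectionError(f"residue {residue_seq} not found")
    z = float(frame.xyz[mask][:, 2].mean())
    return classify_z(z, geometry)


def classify_z(z: float, geometry: MembraneFrameGeometry) -> str:
    """Classify a z coordinate into the M, HG or C slab."""
    lo_m, hi_m = geometry.tail_interval
    if lo_m < z < hi_m:
        return "M"
    if abs(z - geometry.upper_head_z) <= geometry.hg_halfwidth:
        return "HG"
    if abs(z - geometry.lower_head_z) <= geometry.hg_halfwidth:
        return "HG"
    return "C"


def peptide_location_string(frame: StructureModel,
                            residue_range: tuple[int, int],
                            geometry: MembraneFrameGeometry) -> str:
    """Ordered region traversal of a peptide from N- to C-terminus.

    Consecutive identical regions collapse to one symbol; revisits are
    kept, so a peptide running membrane → head groups → membrane reads
    ``"M-HG-M"``.
    """
    lo, hi = residue_range
    if lo > hi:
        raise ValueError("empty residue range")
    present = [rs for rs in range(lo, hi + 1)
               if ((frame.residue_seq == rs) & (frame.role != "lipid")).any()]
    if not present:
        raise SelectionError(f"no residues of {lo}-{hi} found")
    regions = [residue_region(frame, rs, geometry) for rs in present]
    collapsed = [regions[0]]
    for r in regions[1:]:
        if r != collapsed[-1]:
            collapsed.append(r)
    return "-".join(collapsed)


# ---------------------------------------------------------------------------
# contact counting

@dataclass
class ContactTable:
    """Counts of residue–lipid-part contacts by residue category."""

    counts: pd.DataFrame                 # categories × lipid parts
    per_residue: pd.DataFrame            # residue_seq × lipid parts (bool)


def _lipid_part_of(atom_name: str,
                   part_atoms: dict[str, tuple[str, ...]]) -> str | None:
    for part, names in part_atoms.items():
        if atom_name in names:
            return part
    return None


def count_contacts(frame: StructureModel, cutoff: float = 4.0,
                   part_atoms: dict[str, tuple[str, ...]] | None = None
                   ) -> ContactTable:
    """Contact table for one frame (strict ``< cutoff`` on heavy atoms).

    A protein residue contributes at most one contact per lipid part per
    frame, regardless of how many atom pairs are within the cutoff.
    Residues outside the six categories (H, C, M, A) appear in the
    per-residue table but not in the category counts.
    """
    parts = part_atoms or LIPID_PART_ATOMS
    heavy = frame.is_heavy()
    prot = (frame.role == "protein") & heavy
    lip = (frame.role == "lipid") & heavy
    cats = list(RESIDUE_CATEGORIES)
    counts = pd.DataFrame(0, index=cats, columns=list(LIPID_PARTS))

    prot_idx = np.flatnonzero(prot)
    residue_rows = {}
    if prot_idx.size and lip.any():
        part_of = np.array([_lipid_part_of(nm, parts) or ""
                            for nm in frame.atom_name])
        trees = {}
        for part in LIPID_PARTS:
            pmask = lip & (part_of == part)
            if pmask.any():
                trees[part] = cKDTree(frame.xyz[pmask])
        for rs in np.unique(frame.residue_seq[prot_idx]):
            rmask = prot & (frame.residue_seq == rs)
            pts = frame.xyz[rmask]
            row = {}
            for part in LIPID_PARTS:
                tree = trees.get(part)
                touch = bool(tree is not None
                             and (tree.query(pts, k=1)[0] < cutoff).any())
                row[part] = touch
            residue_rows[int(rs)] = row
            cat = residue_category(str(frame.residue_name[rmask][0]))
            if cat is not None:
                for part in LIPID_PARTS:
                    if row[part]:
                        counts.loc[cat, part] += 1
    per_residue = pd.DataFrame.from_dict(residue_rows, orient="index",
                                         columns=list(LIPID_PARTS))
    per_residue.index.name = "residue_seq"
    return ContactTable(counts=counts, per_residue=per_residue.sort_index())


def percent_domain_in_contact(traj: Trajectory,
                              domain_range: tuple[int, int],
                              cutoff: float = 4.0) -> tuple[float, float]:
    """Mean ± s.d. over frames of the % of domain residues touching lipids.

    A residue is "in contact" in a frame if it contacts any lipid part.
    """
    lo, hi = domain_range
    if lo > hi:
        raise ValueError("empty domain range")
    fracs = []
    for i in range(traj.n_frames):
        fr = traj.frame(i)
        table = count_contacts(fr, cutoff=cutoff)
        dom = table.per_residue.loc[
            (table.per_residue.index >= lo) & (table.per_residue.index <= hi)]
        if len(dom) == 0:
            raise SelectionError(f"no domain residues {lo}-{hi} in frame {i}")
        fracs.append(100.0 * dom.any(axis=1).mean())
    fr_arr = np.asarray(fracs)
    return float(fr_arr.mean()), float(fr_arr.std())


def area_per_lipid(frame: StructureModel, leaflet: str = "upper",
                   geometry: MembraneFrameGeometry | None = None) -> float:
    """Box xy-area divided by the number of lipids in the leaflet (Ų).

    The protein footprint is ignored (naive box/leaflet-count estimator).
    """
    if frame.box is None:
        raise GeometryError("periodic box dimensions are required")
    geo = geometry or frame_geometry(frame)
    n = sum(1 for side in geo.leaflet.values() if side == leaflet)
    if n == 0:
        raise GeometryError(f"no lipids in {leaflet} leaflet")
    return float(frame.box[0] * frame.box[1] / n)


def gate_membrane_distance(frame: StructureModel,
                           ring_residues: tuple[int, ...] = (100, 114, 476),
                           reference_atoms: tuple[str, ...] | None = None
                           ) -> dict[int, float]:
    """Signed z distance of each phenyl-ring centre to the head-group plane.

    The reference is the mean z of the upper-leaflet head-group reference
    atoms (the choline nitrogens of the toy lipid by default); negative
    values mean the ring sits below the reference, toward the bilayer.
    """
    from .gate import ring_center
    refs = reference_atoms or ("N4",)
    lip = frame.role == "lipid"
    ref_mask = lip & np.isin(frame.atom_name, refs)
    if not ref_mask.any():
        raise SelectionError(f"no head-group reference atoms {refs} found")
    mid_z = frame.xyz[lip][:, 2].mean()
    upper = ref_mask & (frame.xyz[:, 2] > mid_z)
    if not upper.any():
        raise SelectionError("no upper-leaflet reference atoms found")
    ref_z = float(frame.xyz[upper][:, 2].mean())
    return {rs: float(ring_center(frame, rs)[2] - ref_z) for rs in ring_residues}
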
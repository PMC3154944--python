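"""Coarse-grain mapping, elastic networks, linker randomisation, backmapping.

The coarse-grain representation used here places one bead at the centroid
of the non-hydrogen atoms it represents.  Protein tertiary structure in CG
simulations is maintained by an elastic network: harmonic springs between
backbone beads closer than a cutoff (default 7 Å, strict inequality, with
spring constant k = 10.75 kcal mol⁻¹ Å⁻²), optionally with a residue range
(the membrane-anchor linker) decoupled from the network so its backbone
can move freely.

Reconstruction of atomistic lipids from CG beads ("backmapping") is done
by exhaustive template fitting: a library of atomistic lipid conformers
sharing one atom naming is searched for the conformer whose precomputed
bead centroids, after optimal rigid superposition onto the CG beads, give
the lowest bead RMSD.  The quality criterion is ``conversion_rmsd``: the
RMSD between the CG bead positions and the beads recomputed from the
reconstructed atomistic molecule (acceptably below 1.5 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import kabsch, rmsd, rotation_about_axis
from .structio import StructureModel, assign_roles

# mapping: residue name -> list of (bead_name, member heavy-atom names)
CGMapping = dict[str, list[tuple[str, tuple[str, ...]]]]


class MappingError(ValueError):
    """Raised when a residue or bead topology cannot be mapped."""


class GenerationError(RuntimeError):
    """Raised when conformer generation cannot satisfy its constraints."""


#: Default protein mapping: one backbone bead (N, CA, C, O) per residue and
#: one side-chain bead for everything else (heavy atoms only).
PROTEIN_BB_SC_MAPPING: CGMapping = {"*protein*": [
    ("BB", ("N", "CA", "C", "O")),
    ("SC", ("*",)),
]}


@dataclass
class CGModel:
    """Beads of a coarse-grained molecule (coordinates in Å)."""

    bead_name: np.ndarray     # (n,) str
    residue_seq: np.ndarray   # (n,) int
    residue_name: np.ndarray  # (n,) str
    xyz: np.ndarray           # (n, 3) float
    backbone: np.ndarray      # (n,) bool

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        n = self.xyz.shape[0]
        for name in ("bead_name", "residue_seq", "residue_name", "backbone"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)

    @property
    def n_beads(self) -> int:
        return self.xyz.shape[0]

    def topology_key(self) -> tuple:
        """Hashable bead topology: ordered (residue, bead name) pairs."""
        return tuple(zip(self.residue_name.tolist(), self.bead_name.tolist()))

    def with_coords(self, xyz: np.ndarray) -> "CGModel":
        return CGModel(self.bead_name, self.residue_seq, self.residue_name,
                       np.array(xyz, dtype=float, copy=True), self.backbone)


def _residue_blocks(model: StructureModel):
    """Yield (residue_seq, residue_name, atom index array) in file order."""
    seen = {}
    order = []
    for i, (rs, rn) in enumerate(zip(model.residue_seq, model.residue_name)):
        key = (int(rs), str(rn))
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(i)
    for key in order:
        yield key[0], key[1], np.array(seen[key])


def cg_map(model: StructureModel, mapping: CGMapping) -> CGModel:
    """Map an atomistic model to CG beads at heavy-atom centroids.

    ``mapping`` assigns each residue name a list of beads with their member
    atom names; the wildcard entry ``"*protein*"`` applies to any standard
    amino acid, and a member list of ``("*",)`` collects all heavy atoms of
    the residue not claimed by an earlier bead.  Hydrogens never enter a
    bead.  A residue whose name has no mapping entry raises
    :class:`MappingError` naming the residue.
    """
    heavy = model.is_heavy()
    names, res_seq, res_name, xyz, backbone = [], [], [], [], []
    for rs, rn, idx in _residue_blocks(model):
        entry = mapping.get(rn)
        if entry is None and model.role[idx[0]] == "protein":
            entry = mapping.get("*protein*")
        if entry is None:
            raise MappingError(f"residue {rn} {rs} has no CG mapping entry")
        idx = idx[heavy[idx]]
        claimed = np.zeros(len(idx), dtype=bool)
        atom_names = model.atom_name[idx]
        for bead, members in entry:
            if members == ("*",):
                sel = ~claimed
            else:
                sel = np.isin(atom_names, members) & ~claimed
            if not sel.any():
                continue  # bead absent in this residue (e.g. glycine SC)
            claimed |= sel
            names.append(bead)
            res_seq.append(rs)
            res_name.append(rn)
            xyz.append(model.xyz[idx[sel]].mean(axis=0))
            backbone.append(bead == "BB")
    return CGModel(
        bead_name=np.array(names), residue_seq=np.array(res_seq),
        residue_name=np.array(res_name), xyz=np.array(xyz),
        backbone=np.array(backbone, dtype=bool),
    )


# ---------------------------------------------------------------------------
# elastic network

@dataclass
class ElasticNetwork:
    """Harmonic springs between backbone beads (rest lengths at build time)."""

    springs: list            # (i, j, rest length Å) with i < j, bead indices
    k: float = 10.75         # kcal mol^-1 Å^-2
    cutoff: float = 7.0
    excluded_residues: tuple[int, int] | None = None


def build_elastic_network(cg: CGModel, cutoff: float = 7.0, k: float = 10.75,
                          excluded: tuple[int, int] | None = None) -> ElasticNetwork:
    """Springs between backbone bead pairs strictly closer than ``cutoff``.

    Beads of residues inside ``excluded`` (inclusive range, e.g. the
    membrane-anchor linker) receive no springs at all — they are decoupled
    from the network.
    """
    bb = np.flatnonzero(cg.backbone)
    if len(bb) == 0:
        raise MappingError("CG model has no backbone beads")
    if excluded is not None:
        lo, hi = excluded
        keep = ~((cg.residue_seq[bb] >= lo) & (cg.residue_seq[bb] <= hi))
        bb = bb[keep]
    springs = []
    xyz = cg.xyz
    for a in range(len(bb)):
        i = bb[a]
        d = np.linalg.norm(xyz[bb[a + 1:]] - xyz[i], axis=1)
        for off in np.flatnonzero(d < cutoff):  # strict: ties at cutoff excluded
            j = bb[a + 1 + off]
            springs.append((int(i), int(j), float(d[off])))
    return ElasticNetwork(springs=springs, k=k, cutoff=cutoff,
                          excluded_residues=excluded)


# ---------------------------------------------------------------------------
# linker randomisation

_BACKBONE_ORDER = {"N": 0, "CA": 1, "C": 2, "O": 3}


def _downstream_mask(model: StructureModel, linker: tuple[int, int],
                     pivot_res: int, pivot_atom: str) -> np.ndarray:
    """Atoms that move when rotating about the bond ending at ``pivot_atom``.

    Everything later in the chain moves: atoms of ``pivot_res`` that follow
    the pivot atom in backbone order (the carbonyl O moves with C), all
    later linker residues, and every residue beyond the linker (the rigid
    body).  Residues before the linker (the membrane anchor) stay fixed.
    """
    rank = _BACKBONE_ORDER[pivot_atom]
    later_in_res = np.array([
        _BACKBONE_ORDER.get(nm, 99) > rank for nm in model.atom_name])
    same = model.residue_seq == pivot_res
    after = model.residue_seq > pivot_res
    # residue numbering is only meaningful within the protein chain; lipids
    # and solvent may reuse the same residue numbers and must never move
    chain = np.isin(model.role, ["protein", "heme"])
    return ((same & later_in_res) | after) & chain


def randomize_linker(model: StructureModel, linker: tuple[int, int],
                     n_conformers: int, seed: int = 0,
                     clash_cutoff: float = 3.0,
                     max_attempts_per_conformer: int = 200
                     ) -> list[StructureModel]:
    """Conformers differing only by rotations about linker backbone dihedrals.

    For every linker residue the two backbone dihedral bonds (N–CA and
    CA–C) are rotated by independent uniform angles in (−180°, 180°].
    Bond lengths and angles are untouched (pure rotations about existing
    bonds); the body downstream of the linker moves rigidly.  Conformers
    in which any moved heavy atom comes closer than ``clash_cutoff`` to a
    fixed heavy atom (membrane or anchor) are rejected and redrawn; if a
    conformer cannot be produced within the attempt budget a
    :class:`GenerationError` reports the attempts made.
    """
    lo, hi = linker
    rng = np.random.default_rng(seed)
    heavy = model.is_heavy()
    chain = np.isin(model.role, ["protein", "heme"])
    rigid_mask = (model.residue_seq > hi) & chain  # moved by every rotation
    if not rigid_mask.any():
        raise MappingError("no atoms downstream of the linker")

    bonds = []  # (axis atom a index, axis atom b index, downstream mask)
    for res in range(lo, hi + 1):
        in_res = model.residue_seq == res
        for a_name, b_name in (("N", "CA"), ("CA", "C")):
            ia = np.flatnonzero(in_res & chain & (model.atom_name == a_name))
            ib = np.flatnonzero(in_res & chain & (model.atom_name == b_name))
            if len(ia) == 0 or len(ib) == 0:
                raise MappingError(
                    f"linker residue {res} lacks backbone atom {a_name}/{b_name}")
            bonds.append((int(ia[0]), int(ib[0]),
                          _downstream_mask(model, linker, res, b_name)))

    fixed_heavy = np.flatnonzero(
        heavy & ((chain & (model.residue_seq < lo)) | (model.role == "lipid")))
    out = []
    attempts = 0
    for _ in range(n_conformers):
        for _attempt in range(max_attempts_per_conformer):
            attempts += 1
            xyz = model.xyz.copy()
            for ia, ib, down in bonds:
                angle = rng.uniform(-180.0, 180.0)
                axis = xyz[ib] - xyz[ia]
                R = rotation_about_axis(axis, angle)
                pivot = xyz[ib]
                xyz[down] = (xyz[down] - pivot) @ R.T + pivot
            moved_heavy = xyz[heavy & rigid_mask]
            if len(fixed_heavy) and len(moved_heavy):
                from scipy.spatial import cKDTree
                dmin = cKDTree(xyz[fixed_heavy]).query(moved_heavy, k=1)[0].min()
                if dmin < clash_cutoff:
                    continue
            out.append(model.with_coords(xyz))
            break
        else:
            raise GenerationError(
                f"could not generate conformer {len(out) + 1} clash-free "
                f"after {attempts} total attempts")
    return out


# ---------------------------------------------------------------------------
# lipid template library and backmapping

#: Heavy atoms of the idealized template lipid, in chain order.
#: Main chain: N4–P–C1–C2–C3–A1–A2–A3–A4–A5; branch B1–B2–B3 hangs off C3.
_TEMPLATE_LIPID_CHAIN = ("N4", "P", "C1", "C2", "C3",
                         "A1", "A2", "A3", "A4", "A5")
_TEMPLATE_LIPID_BRANCH = ("B1", "B2", "B3")
_TEMPLATE_ELEMENTS = {"N4": "N", "P": "P", "C1": "C", "C2": "C", "C3": "C",
                      "A1": "C", "A2": "C", "A3": "C", "A4": "C", "A5": "C",
                      "B1": "C", "B2": "C", "B3": "C"}

#: CG mapping of the template lipid: head, glycerol, and two tail beads.
TEMPLATE_LIPID_MAPPING: CGMapping = {"TLP": [
    ("HD", ("N4", "P")),
    ("GL", ("C1", "C2", "C3")),
    ("TA", ("A1", "A2", "A3", "A4", "A5")),
    ("TB", ("B1", "B2", "B3")),
]}


def _ideal_template_lipid() -> StructureModel:
    """Extended (all-trans zigzag) conformation of the template lipid."""
    coords = {}
    step = 1.4
    for k, name in enumerate(_TEMPLATE_LIPID_CHAIN):
        coords[name] = np.array([0.5 * (k % 2), 0.0, -step * k])
    c3 = coords["C3"]
    for k, name in enumerate(_TEMPLATE_LIPID_BRANCH):
        coords[name] = c3 + np.array([1.2 + 0.4 * (k % 2), 0.8, -step * (k + 1)])
    names = list(_TEMPLATE_LIPID_CHAIN) + list(_TEMPLATE_LIPID_BRANCH)
    n = len(names)
    res_name = np.full(n, "TLP")
    return StructureModel(
        atom_id=np.arange(1, n + 1),
        atom_name=np.array(names),
        element=np.array([_TEMPLATE_ELEMENTS[nm] for nm in names]),
        residue_seq=np.ones(n, dtype=int),
        residue_name=res_name,
        chain=np.full(n, "L"),
        xyz=np.array([coords[nm] for nm in names]),
        role=np.full(n, "lipid"),
    )


@dataclass
class LipidTemplateLibrary:
    """Atomistic lipid conformers sharing one atom naming and bead topology."""

    conformers: list                 # of StructureModel
    mapping: CGMapping
    bead_centroids: np.ndarray = field(init=False)   # (n_conf, n_beads, 3)
    topology_key: tuple = field(init=False)

    def __post_init__(self):
        cgs = [cg_map(c, self.mapping) for c in self.conformers]
        keys = {cg.topology_key() for cg in cgs}
        if len(keys) != 1:
            raise MappingError("library conformers map to different bead topologies")
        self.topology_key = keys.pop()
        self.bead_centroids = np.stack([cg.xyz for cg in cgs])

    def __len__(self) -> int:
        return len(self.conformers)


def generate_lipid_template_library(n_conformers: int = 200,
                                    seed: int = 0,
                                    mapping: CGMapping | None = None
                                    ) -> LipidTemplateLibrary:
    """Library of lipid conformers by random dihedral sampling.

    Starting from the extended template lipid, every bond of the main
    chain and the branch is rotated by an independent uniform angle; the
    first conformer is the unmodified extended structure, so the library
    always contains its own reference geometry.
    """
    rng = np.random.default_rng(seed)
    base = _ideal_template_lipid()
    mapping = mapping or TEMPLATE_LIPID_MAPPING
    name_to_idx = {nm: i for i, nm in enumerate(base.atom_name)}

    # rotatable bonds with their downstream atom sets
    bonds = []
    chain = _TEMPLATE_LIPID_CHAIN
    for k in range(len(chain) - 1):
        down = set(chain[k + 2:])
        if chain[k + 1] == "C3" or chain[k] == "C3":
            down |= set(_TEMPLATE_LIPID_BRANCH)
        if chain[k + 1] == "C2":
            down |= set(_TEMPLATE_LIPID_BRANCH)
        if down:
            bonds.append((name_to_idx[chain[k]], name_to_idx[chain[k + 1]],
                          np.array([name_to_idx[nm] for nm in sorted(down)])))
    br = ("C3",) + _TEMPLATE_LIPID_BRANCH
    for k in range(len(br) - 1):
        down = br[k + 2:]
        if down:
            bonds.append((name_to_idx[br[k]], name_to_idx[br[k + 1]],
                          np.array([name_to_idx[nm] for nm in down])))

    conformers = [base]
    for _ in range(n_conformers - 1):
        xyz = base.xyz.copy()
        for ia, ib, down in bonds:
            R = rotation_about_axis(xyz[ib] - xyz[ia], rng.uniform(-180.0, 180.0))
            pivot = xyz[ib]
            xyz[down] = (xyz[down] - pivot) @ R.T + pivot
        conformers.append(base.with_coords(xyz))
    return LipidTemplateLibrary(conformers=conformers, mapping=mapping)


@dataclass
class BackmapResult:
    model: StructureModel        # fitted atomistic lipid
    conformer_index: int
    fit_rmsd: float              # bead RMSD of the winning fit (Å)


def backmap_lipid(cg_lipid: CGModel, library: LipidTemplateLibrary) -> BackmapResult:
    """Reconstruct an atomistic lipid from CG beads by exhaustive template fit.

    Every library conformer's bead centroids are rigid-body superposed onto
    the CG bead positions; the conformer with the smallest bead RMSD wins
    and its atoms are returned in the fitted pose.
    """
    if cg_lipid.topology_key() != library.topology_key:
        raise MappingError("CG lipid bead topology does not match the library")
    target = cg_lipid.xyz
    best = (np.inf, -1, None, None)
    for k, centroids in enumerate(library.bead_centroids):
        R, t = kabsch(centroids, target)
        fitted = centroids @ R.T + t
        r = rmsd(fitted, target)
        if r < best[0]:
            best = (r, k, R, t)
    r, k, R, t = best
    conf = library.conformers[k]
    fitted_model = conf.with_coords(conf.xyz @ R.T + t)
    return BackmapResult(model=fitted_model, conformer_index=k, fit_rmsd=float(r))


def conversion_rmsd(cg_lipid: CGModel, atomistic: StructureModel,
                    mapping: CGMapping, per_bead: bool = False):
    """RMSD between CG beads and beads recomputed from an atomistic lipid.

    This is the backmapping quality criterion: the reconstructed molecule
    is mapped back to beads and compared with the CG input.  With
    ``per_bead=True`` the per-bead deviations (Å) are returned alongside
    the whole-molecule RMSD.
    """
    remapped = cg_map(atomistic, mapping)
    if remapped.topology_key() != cg_lipid.topology_key():
        raise MappingError("atomistic molecule maps to a different bead topology")
    whole = rmsd(remapped.xyz, cg_lipid.xyz)
    if per_bead:
        dev = np.linalg.norm(remapped.xyz - cg_lipid.xyz, axis=1)
        return whole, dict(zip(cg_lipid.bead_name.tolist(), dev.tolist()))
    return whole
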
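"""Structure and trajectory containers with PDB/GRO input and output.

The containers are deliberately light: a :class:`StructureModel` is a set of
parallel numpy arrays over atoms (names, residues, coordinates in Å, and a
role tag), and a :class:`Trajectory` is one topology shared by an ordered
stack of coordinate frames.  File parsing and writing are delegated to
biotite; GRO coordinates (nm) are converted to Å on read.

Residue numbering is kept exactly as found in the file — every residue
range used by the analysis modules (orientation windows, gate residues,
tunnel entrances) is interpreted in the file's own numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants

ROLES = ("protein", "lipid", "heme", "solvent", "other")


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class SelectionError(ValueError):
    """Raised for malformed selection expressions or empty required sets."""


def _infer_element(atom_name: str) -> str:
    """Element symbol from an atom name (PDB-style heuristics)."""
    name = atom_name.strip()
    if not name:
        return ""
    # two-letter elements that commonly appear in these systems
    upper = name.upper()
    for two in ("FE", "CL", "NA", "MG", "ZN", "BR"):
        if upper.startswith(two) and len(name) >= 2:
            # NA/NB/... in heme are nitrogens, not sodium; only accept
            # two-letter symbols when the remainder is non-alphabetic
            if two in ("NA",) and len(upper) > 2:
                break
            if two == "NA" and len(upper) == 2:
                # ambiguous; heme ring nitrogens are named NA — prefer N
                return "N"
            return two
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


@dataclass
class StructureModel:
    """Atoms of one structure: parallel arrays plus per-atom role tags.

    Coordinates are Å.  ``role`` is one of ``protein``, ``lipid``, ``heme``,
    ``solvent``, ``other`` and is always assigned (see :func:`assign_roles`).
    """

    atom_id: np.ndarray          # (n,) int
    atom_name: np.ndarray        # (n,) str
    element: np.ndarray          # (n,) str
    residue_seq: np.ndarray      # (n,) int
    residue_name: np.ndarray     # (n,) str
    chain: np.ndarray            # (n,) str
    xyz: np.ndarray              # (n, 3) float, Å
    role: np.ndarray             # (n,) str
    box: np.ndarray | None = None  # (3,) box lengths, Å, if known

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (n, 3)")
        n = self.xyz.shape[0]
        for name in ("atom_id", "atom_name", "element", "residue_seq",
                     "residue_name", "chain", "role"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)
        if len(np.unique(self.atom_id)) != n:
            raise ValueError("atom_ids must be unique")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[0]

    def masses(self) -> np.ndarray:
        """Per-atom masses (u) from the element table."""
        return np.array([constants.element_mass(e) for e in self.element])

    def vdw_radii(self) -> np.ndarray:
        """Per-atom van der Waals radii (Å)."""
        return np.array([constants.vdw_radius(e) for e in self.element])

    def is_heavy(self) -> np.ndarray:
        return np.char.upper(self.element.astype(str)) != "H"

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        """Copy of this model with replaced coordinates."""
        return replace(self, xyz=np.array(xyz, dtype=float, copy=True))

    def subset(self, mask_or_indices) -> "StructureModel":
        """New model containing only the given atoms (order preserved)."""
        idx = np.asarray(mask_or_indices)
        return StructureModel(
            atom_id=self.atom_id[idx], atom_name=self.atom_name[idx],
            element=self.element[idx], residue_seq=self.residue_seq[idx],
            residue_name=self.residue_name[idx], chain=self.chain[idx],
            xyz=self.xyz[idx], role=self.role[idx], box=self.box,
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames over one shared topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``frame_interval`` is
    the time between consecutive frames in ps.
    """

    topology: StructureModel
    frames: np.ndarray
    frame_interval: float = 150.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("every frame must match the topology atom count")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> StructureModel:
        """Topology posed at frame ``i``."""
        return self.topology.with_coords(self.frames[i])

    def times(self) -> np.ndarray:
        """Frame times in ps (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def sample_every(self, interval_ps: float) -> "Trajectory":
        """Subsample frames at (multiples of) the given time interval."""
        if interval_ps < self.frame_interval:
            raise ValueError("cannot sample finer than the stored interval")
        step = max(1, int(round(interval_ps / self.frame_interval)))
        return Trajectory(self.topology, self.frames[::step],
                          frame_interval=step * self.frame_interval)


@dataclass
class AtomSelection:
    """Result of evaluating a selection expression: ordered atom indices."""

    indices: np.ndarray
    expression: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# role assignment

def assign_roles(residue_name: np.ndarray,
                 lipid_resnames: set[str] | None = None) -> np.ndarray:
    """Total role assignment by residue name.

    Heme is detected by residue name (HEM/HEME/HEC), lipids by a
    configurable residue-name list, solvent by common water names, protein
    by the 20 standard amino acids; everything else is ``other``.
    """
    lipids = {s.upper() for s in (lipid_resnames or constants.DEFAULT_LIPID_RESIDUE_NAMES)}
    res = np.char.upper(np.asarray(residue_name, dtype=str))
    role = np.full(res.shape, "other", dtype="<U8")
    role[np.isin(res, sorted(constants.STANDARD_AMINO_ACIDS))] = "protein"
    role[np.isin(res, sorted(lipids))] = "lipid"
    role[np.isin(res, sorted(constants.HEME_RESIDUE_NAMES))] = "heme"
    role[np.isin(res, sorted(constants.SOLVENT_RESIDUE_NAMES))] = "solvent"
    return role


# ---------------------------------------------------------------------------
# file input / output (biotite-backed)

def _from_atom_array(arr, lipid_resnames=None, box=None) -> StructureModel:
    n = arr.array_length()
    elements = np.asarray(arr.element, dtype=str)
    names = np.asarray(arr.atom_name, dtype=str)
    fixed = np.array([
        el if el.strip() else _infer_element(nm)
        for el, nm in zip(elements, names)
    ], dtype=str)
    return StructureModel(
        atom_id=np.arange(1, n + 1),
        atom_name=names,
        element=fixed,
        residue_seq=np.asarray(arr.res_id, dtype=int),
        residue_name=np.asarray(arr.res_name, dtype=str),
        chain=np.asarray(arr.chain_id, dtype=str),
        xyz=np.asarray(arr.coord, dtype=float),
        role=assign_roles(np.asarray(arr.res_name, dtype=str), lipid_resnames),
        box=box,
    )


def read_structure(path, format: str | None = None,
                   lipid_resnames: set[str] | None = None) -> StructureModel:
    """Read a single-model PDB or GRO file into a :class:`StructureModel`.

    ``format`` defaults to the file extension.  GRO coordinates are
    converted from nm to Å (biotite does this on read).
    """
    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # element inference handled locally
        if fmt == "pdb":
            import biotite.structure.io.pdb as pdbio
            try:
                f = pdbio.PDBFile.read(str(path))
                arr = f.get_structure(model=1)
            except Exception as exc:
                raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
            box = _box_from(arr)
        elif fmt == "gro":
            import biotite.structure.io.gro as groio
            try:
                f = groio.GROFile.read(str(path))
                arr = f.get_structure(model=1)
            except Exception as exc:
                raise ParseError(f"cannot parse GRO file {path}: {exc}") from exc
            box = _box_from(arr)
        else:
            raise ParseError(f"unknown structure format {fmt!r}")
    return _from_atom_array(arr, lipid_resnames, box)


def _box_from(arr):
    box = getattr(arr, "box", None)
    if box is None:
        return None
    b = np.asarray(box, dtype=float)
    if b.ndim == 3:
        b = b[0]
    return np.diag(b).copy() if b.shape == (3, 3) else None


def read_trajectory(path, frame_interval: float = 150.0,
                    lipid_resnames: set[str] | None = None) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one MODEL per frame)."""
    import biotite.structure.io.pdb as pdbio
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            f = pdbio.PDBFile.read(str(path))
            stack = f.get_structure()  # AtomArrayStack
        except Exception as exc:
            raise ParseError(f"cannot parse multi-model PDB {path}: {exc}") from exc
    if stack.stack_depth() == 0:
        raise ParseError(f"no models in {path}")
    topo = _from_atom_array(stack[0], lipid_resnames, _box_from(stack[0]))
    return Trajectory(topo, np.asarray(stack.coord, dtype=float),
                      frame_interval=frame_interval)


def _to_atom_array(model: StructureModel):
    import biotite.structure as struc
    arr = struc.AtomArray(model.n_atoms)
    arr.coord = model.xyz.astype(np.float32)
    arr.atom_name = model.atom_name.astype(str)
    arr.element = model.element.astype(str)
    arr.res_id = model.residue_seq.astype(int)
    arr.res_name = model.residue_name.astype(str)
    arr.chain_id = np.array([c if c.strip() else "A" for c in model.chain.astype(str)])
    arr.hetero = ~np.isin(model.role, ["protein"])
    if model.box is not None:
        arr.box = np.diag(model.box).astype(np.float32)
    return arr


def write_structure(model: StructureModel, path) -> None:
    """Write a model as a single-model PDB file."""
    import biotite.structure.io.pdb as pdbio
    f = pdbio.PDBFile()
    f.set_structure(_to_atom_array(model))
    f.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio
    arr = _to_atom_array(traj.topology)
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = traj.frames.astype(np.float32)
    f = pdbio.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


# ---------------------------------------------------------------------------
# selection language
#
# Grammar (case-insensitive keywords):
#   expr      := term ("or" term)*
#   term      := factor ("and" factor)*
#   factor    := "not" factor | "(" expr ")" | primitive
#   primitive := "resid" ranges | "name" tokens | "resname" tokens
#              | "element" tokens | "role" token | "chain" tokens
#              | "heavy" | "backbone" | "all"
# ranges: e.g. "285-289" or "12" or "1-5 8 10-12"

_KEYWORDS = {"and", "or", "not", "(", ")", "resid", "name", "resname",
             "element", "role", "chain", "heavy", "backbone", "all"}


def _tokenize(expression: str) -> list[str]:
    out, cur = [], ""
    for ch in expression:
        if ch in "()":
            if cur:
                out.append(cur)
                cur = ""
            out.append(ch)
        elif ch.isspace() or ch == ",":
            if cur:
                out.append(cur)
                cur = ""
        else:
            cur += ch
    if cur:
        out.append(cur)
    return out


class _Parser:
    def __init__(self, tokens: list[str], model: StructureModel):
        self.tokens = tokens
        self.pos = 0
        self.model = model

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("empty selection clause")
        if tok.lower() == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.peek() != ")":
                raise SelectionError("missing closing parenthesis")
            self.next()
            return mask
        return self.primitive()

    def _value_tokens(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek().lower() not in _KEYWORDS:
            vals.append(self.next())
        if not vals:
            raise SelectionError("selection keyword needs at least one value")
        return vals

    def primitive(self) -> np.ndarray:
        m = self.model
        kw = self.next().lower()
        if kw == "all":
            return np.ones(m.n_atoms, dtype=bool)
        if kw == "heavy":
            return m.is_heavy()
        if kw == "backbone":
            return (np.isin(m.atom_name, sorted(constants.BACKBONE_ATOM_NAMES))
                    & (m.role == "protein"))
        if kw == "resid":
            mask = np.zeros(m.n_atoms, dtype=bool)
            for token in self._value_tokens():
                if "-" in token[1:]:  # allow negative single ids
                    lo, _, hi = token.partition("-")
                    try:
                        lo_i, hi_i = int(lo), int(hi)
                    except ValueError as exc:
                        raise SelectionError(f"bad residue range {token!r}") from exc
                    mask |= (m.residue_seq >= lo_i) & (m.residue_seq <= hi_i)
                else:
                    try:
                        mask |= m.residue_seq == int(token)
                    except ValueError as exc:
                        raise SelectionError(f"bad residue id {token!r}") from exc
            return mask
        if kw in ("name", "resname", "element", "chain", "role"):
            attr = {"name": "atom_name", "resname": "residue_name",
                    "element": "element", "chain": "chain", "role": "role"}[kw]
            vals = self._value_tokens()
            if kw == "role":
                bad = [v for v in vals if v.lower() not in ROLES]
                if bad:
                    raise SelectionError(f"unknown role(s) {bad}")
                return np.isin(np.char.lower(m.role.astype(str)),
                               [v.lower() for v in vals])
            if kw == "element":
                return np.isin(np.char.upper(m.element.astype(str)),
                               [v.upper() for v in vals])
            return np.isin(getattr(m, attr), vals)
        raise SelectionError(f"unknown selection keyword {kw!r}")


def select(model: StructureModel, expression: str) -> AtomSelection:
    """Evaluate a selection expression; returns matching atom indices.

    The mini-language supports residue ranges (``resid 285-289``),
    atom-name lists (``name CA CB``), residue names, elements, chains,
    role filters (``role lipid``), ``heavy``, ``backbone``, ``all`` and
    boolean combinations with ``and``/``or``/``not`` and parentheses.
    An empty result is legal.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, model).parse()
    return AtomSelection(indices=np.flatnonzero(mask), expression=expression)
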
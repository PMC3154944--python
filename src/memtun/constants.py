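"""Element tables and residue classifications shared across the package.

Masses are standard atomic weights (u); van der Waals radii follow Bondi.
Unknown elements fall back to carbon values with a warning, since analysis
structures frequently carry nonstandard atom names.
"""

from __future__ import annotations

import warnings

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "FE": 55.845,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "MG": 24.305,
    "ZN": 65.38,
}

# Bondi-style vdW radii (Å); used for clearance fields in tunnel detection.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "FE": 2.00,
    "NA": 2.27,
    "CL": 1.75,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
}

DEFAULT_MASS = ATOMIC_MASSES["C"]
DEFAULT_VDW = VDW_RADII["C"]

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

HEME_RESIDUE_NAMES = {"HEM", "HEME", "HEC"}
SOLVENT_RESIDUE_NAMES = {"HOH", "WAT", "SOL", "TIP", "TIP3", "SPC"}
# Residue names recognised as lipids by default; extendable per call.
DEFAULT_LIPID_RESIDUE_NAMES = {"POPC", "POPE", "DPPC", "DOPC", "DLPC", "LIP"}

BACKBONE_ATOM_NAMES = {"N", "CA", "C", "O"}

# One-letter code per residue, used for residue-category classification.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Residue categories used in the contact analysis.  H, C, M, A are
# deliberately not categorised (their lipid-contact counts are negligible
# for P450-type systems and they are excluded from the summary tables).
RESIDUE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "hydrophobic": ("L", "I", "V"),
    "aromatic": ("F", "Y", "W"),
    "hydrophilic": ("S", "T", "N", "Q"),
    "charged": ("D", "E", "R", "K"),
    "glycine": ("G",),
    "proline": ("P",),
}

PHENYL_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
HEME_RING_NITROGENS = ("NA", "NB", "NC", "ND")


def element_mass(element: str) -> float:
    """Atomic mass in u; unknown elements get the carbon mass with a warning."""
    el = element.upper()
    if el in ATOMIC_MASSES:
        return ATOMIC_MASSES[el]
    warnings.warn(f"Unknown element {element!r}; using carbon mass")
    return DEFAULT_MASS


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Å; unknown elements get the carbon radius."""
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def residue_category(res_name: str) -> str | None:
    """Contact-analysis category for a residue, or None if uncategorised."""
    one = THREE_TO_ONE.get(res_name.upper())
    if one is None:
        return None
    for cat, letters in RESIDUE_CATEGORIES.items():
        if one in letters:
            return cat
    return None
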
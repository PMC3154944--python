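"""Shared fixtures: synthetic systems reused across test modules."""

import numpy as np
import pytest

from memtun import synthetic as syn


@pytest.fixture(scope="session")
def toy_protein():
    return syn.build_toy_anchored_protein()


@pytest.fixture(scope="session")
def toy_bilayer():
    return syn.build_toy_bilayer(8, 8, 8.0, seed=1)


@pytest.fixture(scope="session")
def combined_system(toy_protein, toy_bilayer):
    return syn.combine(toy_protein, toy_bilayer)


@pytest.fixture(scope="session")
def small_system(toy_protein):
    """Protein plus a small bilayer, for trajectory-heavy tests."""
    return syn.combine(toy_protein, syn.build_toy_bilayer(4, 4, 8.0, seed=1))


@pytest.fixture(scope="session")
def template_library():
    from memtun import cg
    return cg.generate_lipid_template_library(n_conformers=80, seed=5)


def random_structure(n_atoms: int, seed: int, box: float = 30.0):
    """Random mixed protein/lipid frame for brute-force oracles."""
    from memtun.structio import StructureModel, assign_roles
    rng = np.random.default_rng(seed)
    res_names = ["LEU", "PHE", "SER", "ASP", "GLY", "PRO", "LIP"]
    names, elements, res_seq, res_name = [], [], [], []
    resid = 0
    while len(names) < n_atoms:
        resid += 1
        rn = res_names[rng.integers(len(res_names))]
        if rn == "LIP":
            atoms = [("P", "P"), ("N4", "N"), ("C21", "C"), ("O22", "O"),
                     ("C31", "C"), ("C32", "C"), ("C33", "C")]
        else:
            atoms = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"),
                     ("CB", "C"), ("HB1", "H")]
        for nm, el in atoms:
            if len(names) >= n_atoms:
                break
            names.append(nm)
            elements.append(el)
            res_seq.append(resid)
            res_name.append(rn)
    n = len(names)
    res_name = np.array(res_name)
    return StructureModel(
        atom_id=np.arange(1, n + 1),
        atom_name=np.array(names),
        element=np.array(elements),
        residue_seq=np.array(res_seq),
        residue_name=res_name,
        chain=np.full(n, "A"),
        xyz=rng.uniform(0, box, size=(n, 3)),
        role=assign_roles(res_name),
        box=np.array([box, box, box]),
    )
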
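"""Shared fixtures: literal PDB texts and tiny constructed objects."""

import numpy as np
import pytest

from pocketvar import read_pdb_string
from pocketvar.scoring import IndicatorVectors

# one residue, five atoms
MINI_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.560   6.351  -6.512  1.00  0.00           C
ATOM      3  C   ALA A   1      13.276   5.259  -5.726  1.00  0.00           C
ATOM      4  O   ALA A   1      12.649   4.319  -5.229  1.00  0.00           O
ATOM      5  CB  ALA A   1      13.120   6.432  -7.934  1.00  0.00           C
END
"""

# two altlocs for CA: A at occupancy 0.60, B at 0.40
ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.500   0.000   0.000  0.60  0.00           C
ATOM      3  CA BSER A   1       1.700   0.100   0.000  0.40  0.00           C
ATOM      4  C   SER A   1       3.000   0.000   0.000  1.00  0.00           C
END
"""

# residues numbered 3, 4, 7 (a numbering gap — only residues with
# coordinates exist)
GAP_PDB = """\
ATOM      1  CA  ALA A   3       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   4       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  CYS A   7       7.600   0.000   0.000  1.00  0.00           C
END
"""

MULTIMODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ENDMDL
END
"""

# ALA, GLY, then selenomethionine deposited as HETATM, then a non-protein
# heteroatom that must be dropped
MSE_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
HETATM    3  CA  MSE A   3       7.600   0.000   0.000  1.00  0.00           C
HETATM    4  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
END
"""


@pytest.fixture
def mini_structure():
    return read_pdb_string(MINI_PDB, "mini")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_structure(rng, n_residues=5, atoms_per_residue=4, structure_id="rand"):
    """Small random-coordinate structure built through the PDB text path."""
    lines = []
    serial = 0
    names = ["N", "CA", "C", "O", "CB", "CG"]
    res_names = ["ALA", "GLY", "SER", "LEU", "LYS", "TRP", "PHE", "VAL"]
    for j in range(n_residues):
        for t in range(atoms_per_residue):
            serial += 1
            x, y, z = rng.uniform(-10, 10, 3)
            lines.append(
                f"ATOM  {serial:5d}  {names[t % len(names)]:<3s} "
                f"{res_names[j % len(res_names)]} A{j + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
    return read_pdb_string("\n".join(lines) + "\n", structure_id)


def make_indicators(atom_ind, atom_res_idx, m, structure_id="s", cutoff=3.75,
                    included=None, amino=None):
    """Hand-build an IndicatorVectors from raw per-atom flags."""
    atom_ind = np.asarray(atom_ind, dtype=np.int8)
    atom_res_idx = np.asarray(atom_res_idx, dtype=np.intp)
    if included is None:
        included = np.ones(len(atom_ind), dtype=bool)
    if amino is None:
        amino = np.ones(m, dtype=bool)
    res = np.zeros(m, dtype=np.int8)
    for a, j in zip(atom_ind, atom_res_idx):
        if a:
            res[j] = 1
    return IndicatorVectors(
        structure_id=structure_id,
        atom_indicators=atom_ind,
        residue_indicators=res,
        cutoff_used=cutoff,
        atom_residue_index=atom_res_idx,
        included_mask=np.asarray(included, dtype=bool),
        residue_is_amino=np.asarray(amino, dtype=bool),
    )


def brute_force_indicators(coords, points, cutoff):
    """Exhaustive atom x point double loop — the scoring oracle."""
    out = np.zeros(len(coords), dtype=np.int8)
    for k, c in enumerate(coords):
        for p in points:
            if np.sqrt(np.sum((c - p) ** 2)) <= cutoff:
                out[k] = 1
                break
    return out
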
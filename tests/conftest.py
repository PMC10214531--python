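import numpy as np
import pytest

from xlmodel.structure import Atom, Residue, StructureModel
from xlmodel.synth import ToySpec, generate_toy_complex


def make_structure(residues, label="fixture"):
    """Build a StructureModel from (chain, number, name, [(atom, element, xyz), ...])."""
    out = []
    for chain, number, name, atoms in residues:
        out.append(Residue(chain, number, name,
                           atoms=[Atom(an, el, np.asarray(xyz, float))
                                  for an, el, xyz in atoms]))
    return StructureModel(out, label=label)


def ca_only(chain, number, name, xyz):
    return (chain, number, name, [("CA", "C", xyz)])


@pytest.fixture(scope="session")
def toy_two_chain():
    """3 helical bodies on 2 chains with flexible linkers; deterministic."""
    return generate_toy_complex(
        ToySpec(n_bodies=3, residues_per_body=30, seed=7, chains=[0, 0, 1]))


@pytest.fixture(scope="session")
def toy_single_body():
    return generate_toy_complex(ToySpec(n_bodies=1, residues_per_body=20, seed=5))


def random_ca_structure(seed, n=40, chains=("A",), box=30.0):
    """Random Calpha-only structure with a residue-type mix of reactive codes."""
    rng = np.random.default_rng(seed)
    names = ["LYS", "ARG", "ASP", "GLU", "SER", "THR", "TYR", "ALA", "LEU", "GLY"]
    residues = []
    per_chain = n // len(chains)
    for chain in chains:
        for i in range(per_chain):
            residues.append(ca_only(chain, i + 1, names[int(rng.integers(len(names)))],
                                    rng.uniform(-box, box, 3)))
    return make_structure(residues, label=f"random{seed}")


MINIMAL_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      7  CB  ALA A   2       5.500   2.600   0.000  1.00  0.00           C
TER
END
"""

WATER_PDB = """\
HETATM    1  O   HOH A 101       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A 102       3.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def water_pdb(tmp_path):
    p = tmp_path / "waters.pdb"
    p.write_text(WATER_PDB)
    return p


# ---------------------------------------------------------------------------
# Hand-built residues with side chains, for contact tests
# ---------------------------------------------------------------------------


def lys_residue(chain, number, base, nz_offset):
    base = np.asarray(base, float)
    return (chain, number, "LYS", [
        ("N", "N", base + [0, 0, 0]), ("CA", "C", base + [1.5, 0, 0]),
        ("C", "C", base + [2.2, 1.3, 0]), ("O", "O", base + [1.6, 2.4, 0]),
        ("CB", "C", base + [2.3, -1.2, 0]),
        ("NZ", "N", base + np.asarray(nz_offset, float)),
    ])


def glu_residue(chain, number, base, oe1_offset):
    base = np.asarray(base, float)
    return (chain, number, "GLU", [
        ("N", "N", base + [0, 0, 0]), ("CA", "C", base + [1.5, 0, 0]),
        ("C", "C", base + [2.2, 1.3, 0]), ("O", "O", base + [1.6, 2.4, 0]),
        ("CB", "C", base + [2.3, -1.2, 0]),
        ("OE1", "O", base + np.asarray(oe1_offset, float)),
        ("OE2", "O", base + np.asarray(oe1_offset, float) + [0.5, 0.9, 0]),
    ])


def ser_residue(chain, number, base, og_offset):
    base = np.asarray(base, float)
    return (chain, number, "SER", [
        ("N", "N", base + [0, 0, 0]), ("CA", "C", base + [1.5, 0, 0]),
        ("C", "C", base + [2.2, 1.3, 0]), ("O", "O", base + [1.6, 2.4, 0]),
        ("OG", "O", base + np.asarray(og_offset, float)),
    ])


def leu_residue(chain, number, base, cd_offset):
    base = np.asarray(base, float)
    return (chain, number, "LEU", [
        ("N", "N", base + [0, 0, 0]), ("CA", "C", base + [1.5, 0, 0]),
        ("C", "C", base + [2.2, 1.3, 0]), ("O", "O", base + [1.6, 2.4, 0]),
        ("CB", "C", base + [2.3, -1.2, 0]),
        ("CD1", "C", base + np.asarray(cd_offset, float)),
    ])
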
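"""Shared fixtures: tiny hand-written PDB texts and synthetic structures."""

import numpy as np
import pytest

from resqa.synthetic import DecoySpec, _TORSIONS, build_backbone

# A minimal 3-residue PDB (Ala-Gly-Ser) with N/CA/C/O backbone atoms.
THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.988   2.838   0.050  1.00  0.00           C
ATOM      7  C   GLY A   2       5.500   2.700   0.100  1.00  0.00           C
ATOM      8  O   GLY A   2       6.100   1.650   0.200  1.00  0.00           O
ATOM      9  N   SER A   3       6.150   3.850   0.050  1.00  0.00           N
ATOM     10  CA  SER A   3       7.600   3.900   0.080  1.00  0.00           C
ATOM     11  C   SER A   3       8.200   5.300   0.120  1.00  0.00           C
ATOM     12  O   SER A   3       7.500   6.310   0.150  1.00  0.00           O
TER
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


@pytest.fixture
def helix15():
    """Ideal 15-residue alpha helix (phi=-57, psi=-47)."""
    return build_backbone("A" * 15, [_TORSIONS["H"]] * 15, model_id="helix15")


@pytest.fixture
def extended15():
    """Single fully extended strand with no partner."""
    return build_backbone("V" * 15, [_TORSIONS["E"]] * 15, model_id="ext15")


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast synthetic study conditions for unit tests."""
    return DecoySpec(n_targets=3, n_decoys=3, length_range=(30, 40), seed=7)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
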
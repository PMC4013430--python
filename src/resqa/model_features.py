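"""Structural properties parsed from a model's own coordinates.

Three per-residue properties feed the feature encoding: 3-state secondary
structure assigned from Kabsch–Sander hydrogen bonds, relative solvent
accessibility from Shrake–Rupley SASA, and the set of long-range spatial
contacts (CA–CA <= 8 Å, sequence separation >= 6 by default).

Secondary structure is assigned by a self-contained re-implementation of
the hydrogen-bond part of the DSSP algorithm: the electrostatic H-bond
energy E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332 kcal/mol with
a -0.5 kcal/mol cutoff, n-turns and beta bridges derived from the bond
matrix, and the 8-state alphabet reduced to 3 states by the usual CASP
mapping H,G,I -> H; E,B -> E; rest -> C. Backbone carbonyl oxygens are
reconstructed when absent and amide hydrogens are always placed
geometrically (N–H anti-parallel to the preceding carbonyl), so models
that ship only N/CA/C/(O) atoms are handled.

A reader for precomputed classic DSSP output files is provided for users
who have DSSP installed; it is never required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

import biotite.structure as _bst

from ._aa import MAX_ASA, ONE_TO_THREE
from .errors import FeatureError, InputError
from .structure_io import ProteinModel

# Kabsch-Sander constants
_HB_FACTOR = 0.084 * 332.0  # kcal/mol * Å
_HB_CUTOFF = -0.5           # kcal/mol
_MIN_DIST = 0.5             # guard against degenerate geometry


@dataclass
class ModelDerivedFeatures:
    """Per-residue properties parsed from one model's coordinates."""

    ss3: str                    # over {H,E,C}
    rsa: np.ndarray             # in [0,1]
    exposure2: str              # over {e,b}; 'e' iff rsa >= threshold
    contacts: list[list[int]]   # 1-based partner indices, symmetric

    def __post_init__(self):
        L = len(self.ss3)
        if not (len(self.exposure2) == L == len(self.rsa) == len(self.contacts)):
            raise ValueError("inconsistent per-residue feature lengths")


def _backbone(model: ProteinModel):
    """N, CA, C, O coordinate arrays; O reconstructed where absent."""
    L = len(model)
    N = np.empty((L, 3))
    CA = np.empty((L, 3))
    C = np.empty((L, 3))
    O = np.full((L, 3), np.nan)
    for i, res in enumerate(model.residues):
        for name, arr in (("N", N), ("CA", CA), ("C", C)):
            if not res.has_atom(name):
                raise FeatureError(
                    f"residue {res.seq_index} ({res.aa}) lacks backbone atom {name}"
                )
            arr[i] = res.coord(name)
        if res.has_atom("O"):
            O[i] = res.coord("O")
    # Reconstruct missing carbonyl oxygens in the CA(i)-C(i)-N(i+1) plane.
    for i in range(L):
        if np.isnan(O[i]).any():
            if i + 1 < L:
                d = -(_unit(N[i + 1] - C[i]) + _unit(CA[i] - C[i]))
            else:
                d = -(_unit(N[i] - C[i]) + _unit(CA[i] - C[i]))
            O[i] = C[i] + 1.231 * _unit(d)
    return N, CA, C, O


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else v


def _hbond_matrix(model: ProteinModel) -> np.ndarray:
    """Boolean matrix hb[i, j]: H-bond from C=O of residue i to N-H of residue j."""
    N, CA, C, O = _backbone(model)
    L = len(model)
    # Amide H: N-H parallel to previous residue's O->C direction (DSSP convention).
    H = np.full((L, 3), np.nan)
    for j in range(1, L):
        H[j] = N[j] + _unit(C[j - 1] - O[j - 1])

    donor_ok = np.ones(L, dtype=bool)
    donor_ok[0] = False  # no preceding carbonyl to place H
    for j, res in enumerate(model.residues):
        if res.aa == "P":
            donor_ok[j] = False  # proline has no amide hydrogen

    hb = np.zeros((L, L), dtype=bool)
    if L < 2:
        return hb
    rON = np.maximum(cdist(O, N), _MIN_DIST)
    rCN = np.maximum(cdist(C, N), _MIN_DIST)
    with np.errstate(invalid="ignore"):
        rOH = np.maximum(cdist(O, H), _MIN_DIST)
        rCH = np.maximum(cdist(C, H), _MIN_DIST)
    energy = _HB_FACTOR * (1.0 / rON + 1.0 / rCH - 1.0 / rOH - 1.0 / rCN)
    energy = np.where(np.isnan(energy), 0.0, energy)
    hb = energy < _HB_CUTOFF
    hb &= donor_ok[None, :]
    idx = np.arange(L)
    # exclude self and immediate neighbours as donor/acceptor pairs
    hb &= np.abs(idx[:, None] - idx[None, :]) >= 2
    return hb


def assign_secondary_structure(model: ProteinModel) -> str:
    """3-state secondary structure string over {H,E,C}.

    Helices require two consecutive n-turns (n = 3, 4, 5); beta residues
    come from parallel/antiparallel bridge patterns on the H-bond matrix.
    Helix takes precedence over strand, as in DSSP.
    """
    L = len(model)
    hb = _hbond_matrix(model)

    helix = np.zeros(L, dtype=bool)
    for n in (4, 3, 5):
        turn = np.array([i + n < L and hb[i, i + n] for i in range(L)])
        for i in range(1, L):
            if turn[i - 1] and turn[i]:
                helix[i : i + n] = True

    def _hb(a: int, b: int) -> bool:
        return 0 <= a < L and 0 <= b < L and bool(hb[a, b])

    bridge = np.zeros(L, dtype=bool)
    for i in range(L):
        for j in range(i + 3, L):
            para = (_hb(i - 1, j) and _hb(j, i + 1)) or (
                _hb(j - 1, i) and _hb(i, j + 1)
            )
            anti = (_hb(i, j) and _hb(j, i)) or (
                _hb(i - 1, j + 1) and _hb(j - 1, i + 1)
            )
            if para or anti:
                bridge[i] = bridge[j] = True

    out = []
    for i in range(L):
        if helix[i]:
            out.append("H")
        elif bridge[i]:
            out.append("E")
        else:
            out.append("C")
    return "".join(out)


def _to_atom_array(model: ProteinModel) -> _bst.AtomArray:
    names, elements, res_ids, res_names, coords = [], [], [], [], []
    for res in model.residues:
        three = ONE_TO_THREE.get(res.aa, "UNK")
        for name, xyz in res.atoms.items():
            if name.startswith("H") or name[:1].isdigit():
                continue  # heavy atoms only
            names.append(name)
            elements.append(next((c for c in name if c.isalpha()), "C"))
            res_ids.append(res.seq_index)
            res_names.append(three)
            coords.append(xyz)
    arr = _bst.AtomArray(len(names))
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.full(len(names), "A")
    arr.res_id = np.asarray(res_ids)
    arr.res_name = np.asarray(res_names)
    arr.atom_name = np.asarray(names)
    arr.element = np.asarray(elements)
    arr.hetero = np.zeros(len(names), dtype=bool)
    return arr


def compute_relative_accessibility(
    model: ProteinModel,
    probe_radius: float = 1.4,
    threshold: float = 0.25,
    point_number: int = 500,
) -> tuple[np.ndarray, str]:
    """Per-residue relative solvent accessibility and 2-state exposure.

    SASA is computed by Shrake–Rupley sphere sampling over the heavy atoms
    (via biotite) and normalised by the Tien et al. theoretical maximum ASA
    of each residue type; RSA is clamped to [0, 1]. ``exposure2[i]`` is 'e'
    iff ``rsa[i] >= threshold`` (equality counts as exposed).
    """
    arr = _to_atom_array(model)
    atom_sasa = _bst.sasa(
        arr, probe_radius=probe_radius, point_number=point_number, vdw_radii="Single"
    )
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    rsa = np.zeros(len(model))
    for i, res in enumerate(model.residues):
        mask = arr.res_id == res.seq_index
        rsa[i] = atom_sasa[mask].sum() / MAX_ASA.get(res.aa, MAX_ASA["X"])
    rsa = np.clip(rsa, 0.0, 1.0)
    exposure2 = "".join("e" if r >= threshold else "b" for r in rsa)
    return rsa, exposure2


def observed_contacts(
    model: ProteinModel,
    min_separation: int = 6,
    max_distance: float = 8.0,
    atom: str = "CA",
) -> list[list[int]]:
    """Symmetric per-residue contact partner lists (1-based indices).

    Pair (i, j) is a contact iff |i - j| >= min_separation and the chosen
    atoms are within max_distance; both thresholds inclusive.
    """
    xyz = model.coords(atom)
    L = len(model)
    dist = cdist(xyz, xyz)
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    mask = (sep >= min_separation) & (dist <= max_distance)
    return [list((np.nonzero(mask[i])[0] + 1)) for i in range(L)]


def derive_features(
    model: ProteinModel,
    probe_radius: float = 1.4,
    exposure_threshold: float = 0.25,
    min_separation: int = 6,
    max_distance: float = 8.0,
    contact_atom: str = "CA",
    sasa_points: int = 500,
) -> ModelDerivedFeatures:
    """Bundle SS, RSA/exposure and contacts for one model."""
    ss3 = assign_secondary_structure(model)
    rsa, exposure2 = compute_relative_accessibility(
        model, probe_radius=probe_radius, threshold=exposure_threshold,
        point_number=sasa_points,
    )
    contacts = observed_contacts(
        model, min_separation=min_separation, max_distance=max_distance,
        atom=contact_atom,
    )
    return ModelDerivedFeatures(ss3=ss3, rsa=rsa, exposure2=exposure2, contacts=contacts)


_DSSP_8TO3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def read_dssp_output(path) -> tuple[str, np.ndarray]:
    """Read a classic fixed-column DSSP output file.

    Returns the 3-state secondary-structure string and the raw ACC column.
    Chain breaks ('!') are skipped. This is an optional convenience for
    users who have DSSP; the package's own assignment never shells out.
    """
    ss, acc = [], []
    with open(path) as fh:
        in_data = False
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_data = True
                continue
            if not in_data or len(line) < 38:
                continue
            if line[13] == "!":
                continue
            ss.append(_DSSP_8TO3.get(line[16], "C"))
            try:
                acc.append(float(line[34:38]))
            except ValueError:
                raise InputError(f"bad ACC field in DSSP file {path}: {line!r}")
    if not ss:
        raise InputError(f"no residue rows found in DSSP file {path}")
    return "".join(ss), np.asarray(acc)
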
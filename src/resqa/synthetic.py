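"""Synthetic natives, decoys and noisy annotation files.

This module makes the whole train -> predict -> evaluate loop runnable with
no external data. It emulates the ingredients of a model-accuracy study:

* native structures: backbones (N, CA, C, O, CB) grown residue-by-residue
  from ideal internal coordinates (N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å,
  omega 180°) with segment-appropriate torsions — helix phi/psi = -57/-47°,
  strand -120/+120°, coil sampled from a fixed torsion set — plus a
  self-clash check with resampling;
* decoys: the native perturbed by hinge rotations at random coil positions
  and per-residue rigid displacements whose Gaussian sigma varies smoothly
  along the chain, so each decoy has regions of known, graded error; true
  per-residue deviations are measured by superposing the decoy back onto
  its native;
* "predicted" annotations: the native's parsed secondary structure and
  exposure with state flips applied preferentially at high-deviation
  residues (flip probability sigmoid(logit(rate) + linkage * z), where z is
  the standardised deviation), contact probabilities drawn from Beta
  distributions centred near 1 for native contacts and near 0 for decoy
  pairs, and a PSSM emulated as a noisy one-hot log-odds profile. The
  corruption-deviation linkage is the learnable signal the regressor is
  meant to recover.

Everything is a pure function of (spec, seed). Writers for every input
format (PDB, FASTA, SS/exposure predictions, CASP RR, PSSM) live here as
well, so generated corpora can be round-tripped through the file readers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._aa import ONE_TO_THREE, PSSM_FILE_ORDER
from .errors import InputError, ResqaError
from .model_features import ModelDerivedFeatures, assign_secondary_structure, derive_features
from .prediction_inputs import PredictedAnnotations
from .structure_io import ProteinModel, Residue

# Ideal backbone internal coordinates (Å / degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_CB = 1.521
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.5
_A_N_CA_CB = 110.4
_T_N_CA_CB = -122.6  # torsion C-N-CA-CB for an L-amino acid
_OMEGA = 180.0

_TORSIONS = {"H": (-57.0, -47.0), "E": (-120.0, 120.0)}
# Coil torsion set: polyproline-II-like, bridge, extended-turn and
# left-handed options give varied, mostly clash-free loops.
_COIL_TORSIONS = ((-75.0, 145.0), (-120.0, 130.0), (-90.0, 0.0),
                  (-140.0, 60.0), (-60.0, 140.0))

# State-conditioned residue pools (helix/strand formers; anything in coil).
_SEQ_POOL = {
    "H": "AELMQKRI",
    "E": "VIFYTLW",
    "C": "GNDSTPKQAE",
}


@dataclass
class DecoySpec:
    """Study conditions for one synthetic corpus."""

    n_targets: int = 8
    n_decoys: int = 5
    length_range: tuple[int, int] = (50, 70)
    ss_layout: list[tuple[str, int]] | None = None  # None -> random per target
    # perturbation
    segment_rotation_deg: float = 10.0
    coord_noise_sigma_a: float = 1.5
    hinge_count: int = 1
    # per-decoy quality spread (multiplies coord_noise_sigma_a, cycled)
    decoy_noise_levels: tuple[float, ...] = (0.4, 0.8, 1.3, 1.9, 2.6)
    # annotation noise
    ss_error_rate: float = 0.12
    acc_error_rate: float = 0.12
    contact_noise_concentration: float = 8.0
    deviation_linkage: float = 0.6
    seed: int = 0

    def __post_init__(self):
        for name in ("ss_error_rate", "acc_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0,1]")
        if self.coord_noise_sigma_a < 0 or self.segment_rotation_deg < 0:
            raise InputError("perturbation magnitudes must be >= 0")
        if self.length_range[0] < 10 or self.length_range[1] < self.length_range[0]:
            raise InputError("invalid length range")


@dataclass
class TargetBundle:
    """One synthetic target: native, its parsed truth, annotations, decoys."""

    target_id: str
    native: ProteinModel
    native_feats: ModelDerivedFeatures
    annotations: PredictedAnnotations
    decoys: list[tuple[ProteinModel, np.ndarray]]  # (model, true deviations)
    layout: list[tuple[str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# internal-to-Cartesian backbone construction
# ---------------------------------------------------------------------------

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d with bond c-d, angle b-c-d and torsion a-b-c-d."""
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_backbone(sequence: str, torsions: list[tuple[float, float]],
                   model_id: str = "built") -> ProteinModel:
    """Grow an all-backbone chain (N, CA, C, O, CB) from phi/psi torsions.

    ``torsions[i]`` is (phi_i, psi_i); phi of the first residue is unused.
    """
    L = len(sequence)
    if L == 0:
        raise InputError("empty sequence")
    if len(torsions) != L:
        raise InputError("need one (phi, psi) pair per residue")
    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    # seed geometry for residue 1
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    th = math.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-math.cos(th), math.sin(th), 0.0])
    for i in range(1, L):
        psi_prev = torsions[i - 1][1]
        phi_i = torsions[i][0]
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi_prev)
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA)
        C[i] = _place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi_i)

    residues = []
    for i, aa in enumerate(sequence):
        atoms = {"N": N[i].copy(), "CA": CA[i].copy(), "C": C[i].copy()}
        # carbonyl O in the peptide plane, anti to psi
        psi = torsions[i][1]
        atoms["O"] = _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        if aa != "G":
            atoms["CB"] = _place(C[i], N[i], CA[i], _B_CA_CB, _A_N_CA_CB,
                                 _T_N_CA_CB)
        residues.append(Residue(seq_index=i + 1, aa=aa, atoms=atoms,
                                orig_id=("A", i + 1, " ")))
    return ProteinModel(model_id=model_id, residues=residues)


def _layout_string(layout: list[tuple[str, int]]) -> str:
    return "".join(state * n for state, n in layout)


def random_layout(rng: np.random.Generator, length: int) -> list[tuple[str, int]]:
    """Random alternating coil/secondary-structure layout summing to length."""
    layout: list[tuple[str, int]] = [("C", int(rng.integers(2, 5)))]
    total = layout[0][1]
    while total < length:
        state = "H" if rng.random() < 0.6 else "E"
        n = int(rng.integers(9, 16)) if state == "H" else int(rng.integers(5, 9))
        layout.append((state, n))
        total += n
        nc = int(rng.integers(3, 7))
        layout.append(("C", nc))
        total += nc
    # trim to exact length from the end
    excess = total - length
    trimmed = []
    for state, n in reversed(layout):
        if excess >= n:
            excess -= n
            continue
        trimmed.append((state, n - excess))
        excess = 0
    return [seg for seg in reversed(trimmed) if seg[1] > 0]


def _sample_sequence(rng: np.random.Generator, ss: str) -> str:
    return "".join(
        _SEQ_POOL[s][rng.integers(0, len(_SEQ_POOL[s]))] for s in ss
    )


def _min_nonlocal_ca_dist(model: ProteinModel) -> float:
    ca = model.coords("CA")
    L = len(model)
    idx = np.arange(L)
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    mask = np.abs(idx[:, None] - idx[None, :]) > 2
    return float(d[mask].min()) if mask.any() else np.inf


def _radius_of_gyration(model: ProteinModel) -> float:
    ca = model.coords("CA")
    return float(np.sqrt(((ca - ca.mean(axis=0)) ** 2).sum(axis=1).mean()))


def _compact(
    sequence: str,
    ss: str,
    torsions: list[tuple[float, float]],
    rng: np.random.Generator,
    model_id: str,
    iterations: int = 250,
) -> ProteinModel:
    """Greedy compaction in coil-torsion space.

    Random coil residues get resampled torsions; a proposal is accepted iff
    the chain stays clash-free and the radius of gyration decreases. This
    collapses the initially open chain into a fold-like arrangement with
    genuine long-range contacts and buried residues, without touching the
    helix/strand torsions.
    """
    coil_idx = [i for i, s in enumerate(ss) if s == "C"]
    model = build_backbone(sequence, torsions, model_id=model_id)
    rg = _radius_of_gyration(model)
    if not coil_idx:
        return model
    torsions = list(torsions)
    for _ in range(iterations):
        i = coil_idx[rng.integers(0, len(coil_idx))]
        proposal = _COIL_TORSIONS[rng.integers(0, len(_COIL_TORSIONS))]
        if proposal == torsions[i]:
            continue
        trial = list(torsions)
        trial[i] = proposal
        candidate = build_backbone(sequence, trial, model_id=model_id)
        if _min_nonlocal_ca_dist(candidate) < 3.5:
            continue
        rg_new = _radius_of_gyration(candidate)
        if rg_new < rg:
            torsions, rg, model = trial, rg_new, candidate
    return model


def generate_native(
    spec: DecoySpec,
    target_index: int = 0,
    max_retries: int = 200,
    n_candidates: int = 10,
    compaction_iterations: int = 250,
) -> tuple[ProteinModel, ModelDerivedFeatures, list[tuple[str, int]]]:
    """Build one clash-free, compact native structure plus its parsed truth.

    Coil torsions are resampled until the self-clash check passes
    (min CA-CA >= 3.5 Å for |i-j| > 2); the most compact of
    ``n_candidates`` clash-free chains is then collapsed further by greedy
    coil-torsion moves (:func:`_compact`), emulating a folded protein.
    Deterministic given (spec.seed, target_index). Raises when no
    clash-free chain is found in ``max_retries`` attempts.
    """
    rng = np.random.default_rng([spec.seed, target_index])
    if spec.ss_layout is not None:
        layout = list(spec.ss_layout)
        if sum(n for _, n in layout) == 0:
            raise InputError("ss_layout has zero total length")
    else:
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        layout = random_layout(rng, length)
    ss = _layout_string(layout)
    if len(ss) == 0:
        raise InputError("zero-length layout")
    sequence = _sample_sequence(rng, ss)

    best = None
    best_rg = np.inf
    found = 0
    for _attempt in range(max_retries):
        torsions = []
        for s in ss:
            if s in _TORSIONS:
                torsions.append(_TORSIONS[s])
            else:
                torsions.append(_COIL_TORSIONS[rng.integers(0, len(_COIL_TORSIONS))])
        model = build_backbone(sequence, torsions,
                               model_id=f"T{target_index:03d}_native")
        if _min_nonlocal_ca_dist(model) < 3.5:
            continue
        found += 1
        rg = _radius_of_gyration(model)
        if rg < best_rg:
            best, best_rg, best_torsions = model, rg, torsions
        if found >= n_candidates:
            break
    if best is None:
        raise ResqaError(
            f"could not build a clash-free native for target {target_index} "
            f"after {max_retries} attempts"
        )
    best = _compact(sequence, ss, best_torsions, rng, best.model_id,
                    iterations=compaction_iterations)
    feats = derive_features(best)
    return best, feats, layout


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

def _smooth_profile(rng: np.random.Generator, L: int) -> np.ndarray:
    """Smooth curve in [0, 1] along the chain (sum of random sinusoids)."""
    t = np.linspace(0.0, 1.0, L)
    curve = np.zeros(L)
    for _ in range(3):
        freq = rng.uniform(0.5, 3.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        curve += rng.uniform(0.3, 1.0) * np.sin(2.0 * np.pi * freq * t + phase)
    lo, hi = curve.min(), curve.max()
    return (curve - lo) / (hi - lo) if hi > lo else np.full(L, 0.5)


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def generate_decoy(
    native: ProteinModel,
    spec: DecoySpec,
    seed,
    ss3: str | None = None,
    noise_scale: float = 1.0,
    sigma_profile: np.ndarray | None = None,
    decoy_id: str | None = None,
) -> tuple[ProteinModel, np.ndarray]:
    """Perturb a native into a decoy with known per-residue deviations.

    Hinge rotations are applied at ``spec.hinge_count`` random coil
    positions (everything downstream of the hinge rotates by an angle drawn
    with standard deviation ``segment_rotation_deg``); each residue is then
    displaced rigidly by Gaussian noise whose sigma follows a smooth
    along-chain profile scaled by ``coord_noise_sigma_a * noise_scale``.
    True deviations are measured by superposing the decoy onto the native.
    Deterministic given the seed.
    """
    from .evaluation import superimpose  # local import: avoid cycle

    rng = np.random.default_rng(seed)
    L = len(native)
    if ss3 is None:
        ss3 = assign_secondary_structure(native)
    coords = {
        res.seq_index: {k: v.copy() for k, v in res.atoms.items()}
        for res in native.residues
    }

    # hinge rotations at coil residues away from the termini
    coil = [i for i in range(L) if ss3[i] == "C" and 4 <= i <= L - 5]
    n_hinges = min(spec.hinge_count, len(coil))
    if spec.segment_rotation_deg > 0 and n_hinges > 0:
        hinges = sorted(rng.choice(len(coil), size=n_hinges, replace=False))
        for h in [coil[i] for i in hinges]:
            pivot = coords[h + 1]["CA"].copy()
            angle = math.radians(rng.normal(0.0, spec.segment_rotation_deg))
            axis = rng.normal(size=3)
            rot = _rotation_about_axis(axis, angle)
            for i in range(h + 1, L):
                for name in coords[i + 1]:
                    coords[i + 1][name] = rot @ (coords[i + 1][name] - pivot) + pivot

    # Smooth position-dependent rigid displacement per residue. The raw
    # Gaussian field is smoothed along the chain (unit-norm kernel, so the
    # per-residue variance is preserved) because model errors are locally
    # coherent: neighbouring residues of a misplaced segment move together,
    # which keeps local geometry intact where sigma is small.
    if sigma_profile is None:
        sigma_profile = 0.3 + 1.4 * _smooth_profile(rng, L)
    sigma = spec.coord_noise_sigma_a * noise_scale * np.asarray(sigma_profile)
    raw = rng.normal(0.0, 1.0, size=(L, 3))
    kernel = np.exp(-0.5 * (np.arange(-4, 5) / 2.0) ** 2)
    kernel /= np.linalg.norm(kernel)
    smooth = np.empty_like(raw)
    for k in range(3):
        smooth[:, k] = np.convolve(raw[:, k], kernel, mode="same")
    shifts = smooth * sigma[:, None]
    for i in range(L):
        for name in coords[i + 1]:
            coords[i + 1][name] = coords[i + 1][name] + shifts[i]

    residues = [
        Residue(seq_index=res.seq_index, aa=res.aa,
                atoms=coords[res.seq_index], orig_id=res.orig_id)
        for res in native.residues
    ]
    decoy = ProteinModel(
        model_id=decoy_id or f"{native.model_id}_decoy", residues=residues
    )
    true_dev = superimpose(decoy, native).per_residue_deviation
    return decoy, true_dev


# ---------------------------------------------------------------------------
# annotation corruption
# ---------------------------------------------------------------------------

def _flip_probabilities(
    rate: float, linkage: float, deviations: np.ndarray | None, L: int,
) -> np.ndarray:
    """Per-residue flip probability: sigmoid(logit(rate) + linkage * z).

    Exact at the endpoints (rate 0 -> never, rate 1 -> always); in between,
    residues with larger true deviation are flipped preferentially.
    """
    if rate <= 0.0:
        return np.zeros(L)
    if rate >= 1.0:
        return np.ones(L)
    z = np.zeros(L)
    if deviations is not None and linkage != 0.0:
        d = np.asarray(deviations, dtype=float)
        if d.std() > 0:
            z = (d - d.mean()) / d.std()
    logit = math.log(rate / (1.0 - rate))
    return 1.0 / (1.0 + np.exp(-(logit + linkage * z)))


def corrupt_annotations(
    sequence: str,
    true_feats: ModelDerivedFeatures,
    spec: DecoySpec,
    seed,
    deviations: np.ndarray | None = None,
) -> PredictedAnnotations:
    """Emulate sequence-based predictor output from the parsed truth.

    Secondary-structure and exposure states flip to a uniformly random
    different state with the linkage-weighted probabilities above; contact
    probabilities are Beta-distributed around 0.8 for true contacts and
    around 0.15 for a matched number of random non-contact pairs; the PSSM
    is a noisy one-hot log-odds profile of the sequence.
    """
    rng = np.random.default_rng(seed)
    L = len(sequence)

    p_ss = _flip_probabilities(spec.ss_error_rate, spec.deviation_linkage,
                               deviations, L)
    ss = []
    for i, s in enumerate(true_feats.ss3):
        if rng.random() < p_ss[i]:
            ss.append(rng.choice([t for t in "HEC" if t != s]))
        else:
            ss.append(s)

    p_acc = _flip_probabilities(spec.acc_error_rate, spec.deviation_linkage,
                                deviations, L)
    acc = []
    for i, s in enumerate(true_feats.exposure2):
        if rng.random() < p_acc[i]:
            acc.append("e" if s == "b" else "b")
        else:
            acc.append(s)

    conc = max(spec.contact_noise_concentration, 1e-6)
    prob = np.zeros((L, L))
    true_pairs = [
        (i, j - 1)
        for i, partners in enumerate(true_feats.contacts)
        for j in partners
        if j - 1 > i
    ]
    for i, j in true_pairs:
        p = rng.beta(conc * 0.8, conc * 0.2)
        prob[i, j] = prob[j, i] = p
    candidates = [
        (i, j)
        for i in range(L)
        for j in range(i + 6, L)
        if prob[i, j] == 0.0
    ]
    n_false = min(len(true_pairs), len(candidates))
    if n_false > 0:
        for k in rng.choice(len(candidates), size=n_false, replace=False):
            i, j = candidates[k]
            p = rng.beta(conc * 0.15, conc * 0.85)
            prob[i, j] = prob[j, i] = p

    onehot = np.zeros((L, 20))
    order = {aa: k for k, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}
    for i, aa in enumerate(sequence):
        if aa in order:
            onehot[i, order[aa]] = 1.0
    pssm = np.rint(6.0 * onehot - 2.0 + rng.normal(0.0, 1.5, size=(L, 20)))
    pssm = np.clip(pssm, -9, 13)

    return PredictedAnnotations(
        sequence=sequence,
        ss3_pred="".join(ss),
        exposure2_pred="".join(acc),
        contact_prob=prob,
        pssm=pssm,
    )


# ---------------------------------------------------------------------------
# file writers (formats the readers in prediction_inputs consume)
# ---------------------------------------------------------------------------

def write_pdb(model: ProteinModel, path) -> None:
    """Minimal wwPDB v3.3 ATOM-record writer (single chain, single model)."""
    order = ("N", "CA", "C", "O", "CB")
    with open(path, "w") as fh:
        serial = 1
        for res in model.residues:
            names = [n for n in order if n in res.atoms]
            names += [n for n in res.atoms if n not in order]
            for name in names:
                x, y, z = res.atoms[name]
                element = next((c for c in name if c.isalpha()), "C")
                fh.write(
                    f"ATOM  {serial:5d} {name:^4s} "
                    f"{ONE_TO_THREE.get(res.aa, 'UNK'):>3s} A{res.seq_index:4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}\n"
                )
                serial += 1
        fh.write("TER\nEND\n")


def write_fasta(target_id: str, sequence: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{target_id}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")


def write_ss_pred(ss: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(ss + "\n")


def write_acc_pred(acc: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(acc + "\n")


def write_rr(sequence: str, contact_prob: np.ndarray, path) -> None:
    """CASP RR format: sequence lines then 'i j 0 8 p' rows for p > 0."""
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        for i in range(0, len(sequence), 50):
            fh.write(sequence[i : i + 50] + "\n")
        L = len(sequence)
        for i in range(L):
            for j in range(i + 1, L):
                p = contact_prob[i, j]
                if p > 0.0:
                    fh.write(f"{i + 1} {j + 1} 0 8 {p:.6f}\n")
        fh.write("END\n")


def write_pssm(sequence: str, pssm: np.ndarray, path) -> None:
    """PSI-BLAST ASCII layout (log-odds block only, canonical column order)."""
    alpha_order = "ACDEFGHIKLMNPQRSTVWY"
    reorder = [alpha_order.index(aa) for aa in PSSM_FILE_ORDER]
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "  ".join(PSSM_FILE_ORDER) + "\n")
        for i, aa in enumerate(sequence):
            row = pssm[i, reorder]
            vals = " ".join(f"{int(v):3d}" for v in row)
            # pad with a dummy percentage block so the canonical >=22-token
            # row shape is preserved
            fh.write(f"{i + 1:5d} {aa} {vals} {' '.join(['0'] * 20)} 0.00 0.00\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(spec: DecoySpec) -> list[TargetBundle]:
    """Full synthetic study: natives, graded decoys, corrupted annotations.

    Pure function of (spec, spec.seed). Decoy k of every target uses noise
    level ``decoy_noise_levels[k % len(levels)]`` so each target has a
    spread of model qualities; the per-target annotation corruption is
    linked to the mean deviation profile over that target's decoys.
    """
    corpus = []
    for t in range(spec.n_targets):
        native, feats, layout = generate_native(spec, t)
        target_id = f"T{t:03d}"
        native.model_id = target_id + "_native"
        rng = np.random.default_rng([spec.seed, t, 7919])
        profile = 0.3 + 1.4 * _smooth_profile(rng, len(native))
        decoys = []
        for k in range(spec.n_decoys):
            level = spec.decoy_noise_levels[k % len(spec.decoy_noise_levels)]
            decoy, dev = generate_decoy(
                native,
                spec,
                seed=[spec.seed, t, k, 104729],
                ss3=feats.ss3,
                noise_scale=level,
                sigma_profile=profile,
                decoy_id=f"{target_id}_model_{k}",
            )
            decoys.append((decoy, dev))
        mean_dev = np.mean([dev for _, dev in decoys], axis=0)
        sequence = "".join(res.aa for res in native.residues)
        annotations = corrupt_annotations(
            sequence, feats, spec, seed=[spec.seed, t, 15485863],
            deviations=mean_dev,
        )
        corpus.append(
            TargetBundle(
                target_id=target_id,
                native=native,
                native_feats=feats,
                annotations=annotations,
                decoys=decoys,
                layout=layout,
            )
        )
    return corpus


def write_corpus(corpus: list[TargetBundle], out_dir) -> None:
    """Emit targets/<id>/{native.pdb, model_k.pdb, target.fasta, ss.pred,
    acc.pred, contacts.rr, profile.pssm, truth.tsv}."""
    from pathlib import Path

    root = Path(out_dir)
    for bundle in corpus:
        d = root / "targets" / bundle.target_id
        d.mkdir(parents=True, exist_ok=True)
        write_pdb(bundle.native, d / "native.pdb")
        sequence = bundle.annotations.sequence
        write_fasta(bundle.target_id, sequence, d / "target.fasta")
        write_ss_pred(bundle.annotations.ss3_pred, d / "ss.pred")
        write_acc_pred(bundle.annotations.exposure2_pred, d / "acc.pred")
        write_rr(sequence, bundle.annotations.contact_prob, d / "contacts.rr")
        if bundle.annotations.pssm is not None:
            write_pssm(sequence, bundle.annotations.pssm, d / "profile.pssm")
        with open(d / "truth.tsv", "w") as fh:
            fh.write("model_id\tresidue_index\ttrue_deviation_A\n")
            for model, dev in bundle.decoys:
                write_pdb(model, d / f"{model.model_id.split('_', 1)[1]}.pdb")
                for i, v in enumerate(dev):
                    fh.write(f"{model.model_id}\t{i + 1}\t{v:.6f}\n")
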
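"""Readers for sequence-derived predicted annotations.

These are the files a user obtains from external sequence-based predictors
(secondary structure, 2-state solvent exposure, residue-residue contact
probabilities in CASP RR format, and a PSI-BLAST ASCII PSSM). The package
consumes them as inputs; it never runs the predictors.

All annotations are validated against the target sequence length L and the
contact matrix is kept symmetric with absent pairs read as zero. Profile
columns are reordered from the PSSM file order into the package's fixed
alphabetical amino-acid order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from ._aa import AA_ORDER, PSSM_FILE_ORDER
from .errors import InputError


@dataclass
class PredictedAnnotations:
    """Sequence-based predictions for one target."""

    sequence: str
    ss3_pred: str                      # over {H,E,C}
    exposure2_pred: str                # over {e,b}
    contact_prob: np.ndarray           # (L, L) symmetric, values in [0,1]
    pssm: np.ndarray | None = None     # (L, 20) log-odds, alphabetical columns

    def __post_init__(self):
        L = len(self.sequence)
        if len(self.ss3_pred) != L or len(self.exposure2_pred) != L:
            raise InputError("annotation length does not match sequence length")
        if self.contact_prob.shape != (L, L):
            raise InputError("contact matrix shape does not match sequence length")
        if not np.allclose(self.contact_prob, self.contact_prob.T):
            raise InputError("contact probability matrix is not symmetric")
        if self.pssm is not None and self.pssm.shape != (L, 20):
            raise InputError("PSSM shape does not match sequence length")


def read_fasta(path) -> tuple[str, str]:
    """Single-record FASTA -> (id, uppercase sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise InputError(f"expected exactly one FASTA record in {path}, "
                         f"found {len(records)}")
    seq = str(records[0].seq).upper()
    if not seq:
        raise InputError(f"empty sequence in {path}")
    return records[0].id, seq


def _fasta_like_string(path) -> str:
    chunks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith((">", "#")):
                continue
            chunks.append(line)
    return "".join(chunks)


def read_ss_prediction(path, length: int) -> str:
    """Predicted 3-state secondary structure.

    Accepts either a FASTA-like single string over {H,E,C} or PSIPRED-ss2
    style columns (index, AA, state, pC, pH, pE); for the columnar format
    the state is the argmax of the three probabilities with ties broken in
    the order H > E > C.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) >= 6 and tok[0].isdigit():
                rows.append(tok)
    if rows:
        out = []
        for tok in rows:
            try:
                p_c, p_h, p_e = float(tok[3]), float(tok[4]), float(tok[5])
            except ValueError:
                raise InputError(f"bad probability row in {path}: {tok}")
            if p_h >= p_e and p_h >= p_c:
                out.append("H")
            elif p_e >= p_c:
                out.append("E")
            else:
                out.append("C")
        ss = "".join(out)
    else:
        ss = _fasta_like_string(path).upper()
    if len(ss) != length:
        raise InputError(
            f"SS prediction length {len(ss)} != target length {length} ({path})"
        )
    bad = set(ss) - set("HEC")
    if bad:
        raise InputError(f"unknown secondary-structure letters {bad} in {path}")
    return ss


def read_acc_prediction(path, length: int) -> str:
    """Predicted 2-state exposure: FASTA-like string over {e,b}, case-insensitive."""
    acc = _fasta_like_string(path).lower()
    if len(acc) != length:
        raise InputError(
            f"exposure prediction length {len(acc)} != target length {length} ({path})"
        )
    bad = set(acc) - set("eb")
    if bad:
        raise InputError(f"unknown exposure letters {bad} in {path}")
    return acc


def read_rr_contacts(path, length: int) -> np.ndarray:
    """CASP RR contact file -> dense symmetric (L, L) probability matrix.

    Lines are "i j d1 d2 p" (1-based, i < j); plain "i j p" rows are also
    accepted. Leading sequence lines and RR header/footer keywords are
    ignored. Unlisted pairs are zero; duplicate pairs: last value wins.
    """
    mat = np.zeros((length, length))
    skip_words = {"PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "REMARK", "END"}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            tok = line.split()
            if tok[0].upper() in skip_words:
                continue
            if all(t.isalpha() for t in tok):
                continue  # sequence line
            if len(tok) >= 5:
                i_s, j_s, p_s = tok[0], tok[1], tok[4]
            elif len(tok) == 3:
                i_s, j_s, p_s = tok
            else:
                raise InputError(f"unparsable RR line in {path}: {line!r}")
            try:
                i, j, p = int(i_s), int(j_s), float(p_s)
            except ValueError:
                raise InputError(f"unparsable RR line in {path}: {line!r}")
            if not (1 <= i <= length and 1 <= j <= length) or i == j:
                raise InputError(
                    f"RR pair ({i},{j}) outside 1..{length} in {path}"
                )
            if p < -1e-6 or p > 1 + 1e-6:
                raise InputError(f"RR probability {p} outside [0,1] in {path}")
            p = min(max(p, 0.0), 1.0)
            mat[i - 1, j - 1] = p
            mat[j - 1, i - 1] = p
    return mat


_REORDER = [PSSM_FILE_ORDER.index(aa) for aa in AA_ORDER]


def read_pssm(path, length: int, sequence: str | None = None) -> np.ndarray:
    """PSI-BLAST ASCII PSSM -> (L, 20) log-odds matrix, alphabetical columns.

    Only the first 20 numeric columns (the log-odds block) are used. When
    ``sequence`` is given and the file's residue letters disagree, a warning
    is emitted; the FASTA sequence stays authoritative.
    """
    rows = []
    letters = []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if len(tok) >= 22 and tok[0].isdigit() and len(tok[1]) == 1 and tok[1].isalpha():
                try:
                    vals = [float(t) for t in tok[2:22]]
                except ValueError:
                    raise InputError(f"unparsable PSSM row in {path}: {line!r}")
                rows.append(vals)
                letters.append(tok[1].upper())
    if len(rows) != length:
        raise InputError(
            f"PSSM has {len(rows)} rows, expected {length} ({path})"
        )
    if sequence is not None and "".join(letters) != sequence.upper():
        warnings.warn(
            f"PSSM residue letters disagree with the FASTA sequence ({path}); "
            "using the FASTA sequence",
            stacklevel=2,
        )
    mat = np.asarray(rows)
    return mat[:, _REORDER]


def load_annotations(
    fasta_path, ss_path, acc_path, rr_path, pssm_path=None
) -> PredictedAnnotations:
    """Convenience loader for a full set of per-target annotation files."""
    _, sequence = read_fasta(fasta_path)
    L = len(sequence)
    return PredictedAnnotations(
        sequence=sequence,
        ss3_pred=read_ss_prediction(ss_path, L),
        exposure2_pred=read_acc_prediction(acc_path, L),
        contact_prob=read_rr_contacts(rr_path, L),
        pssm=read_pssm(pssm_path, L, sequence) if pssm_path else None,
    )
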
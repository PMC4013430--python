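"""Reading protein models from PDB files into a validated internal form.

A model is an ordered list of residues renumbered contiguously 1..L;
original PDB numbering (chain, resseq, insertion code) is kept only as
metadata, so that windowing and sequence-separation arithmetic downstream
never see numbering gaps. Parsing is delegated to Bio.PDB: first MODEL
block only, one chain, HETATM records ignored except for a small table of
modified residues (MSE and friends), alternate locations resolved to the
highest-occupancy conformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from ._aa import MODIFIED_TO_ONE, THREE_TO_ONE
from .errors import EmptyStructureError, InputError, PdbFormatError


@dataclass
class Residue:
    """One residue: 1-based contiguous index, one-letter code, atom coordinates."""

    seq_index: int
    aa: str
    atoms: dict[str, np.ndarray]
    orig_id: tuple = ()  # (chain id, resseq, icode) from the source file

    def has_atom(self, name: str) -> bool:
        return name in self.atoms

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name]


@dataclass
class ProteinModel:
    model_id: str
    residues: list[Residue]
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def coords(self, atom: str = "CA") -> np.ndarray:
        """(L, 3) array of the named atom; raises if any residue lacks it."""
        rows = []
        for res in self.residues:
            if atom not in res.atoms:
                raise InputError(
                    f"residue {res.seq_index} ({res.aa}) of {self.model_id} "
                    f"has no {atom} atom"
                )
            rows.append(res.atoms[atom])
        return np.asarray(rows, dtype=float)


@dataclass
class CompletenessReport:
    complete: bool
    missing: set[int] = field(default_factory=set)     # target positions absent
    mismatches: set[int] = field(default_factory=set)  # positions where codes differ
    missing_ca: set[int] = field(default_factory=set)  # model positions without CA
    model_length: int = 0
    target_length: int = 0


def _resolve_aa(resname: str) -> str:
    resname = resname.strip().upper()
    return THREE_TO_ONE.get(resname) or MODIFIED_TO_ONE.get(resname) or "X"


def read_pdb_model(path, chain: str | None = None, model_id: str | None = None) -> ProteinModel:
    """Parse a PDB file into a :class:`ProteinModel`.

    Only the first MODEL block is read; ``chain`` selects a chain id, the
    first chain is used when unspecified. HETATM residues are skipped unless
    they are known modified amino acids (e.g. MSE -> M). Residues are
    renumbered 1..L in file order.
    """
    path = str(path)
    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(model_id or "model", path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise PdbFormatError(f"cannot parse PDB file {path}: {exc}") from exc

    first_model = next(iter(structure), None)
    if first_model is None:
        raise EmptyStructureError(f"no MODEL/ATOM content in {path}")

    chains = list(first_model)
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise InputError(f"chain {chain!r} not found in {path}")
    if not chains:
        raise EmptyStructureError(f"no chains in first model of {path}")
    selected = chains[0]

    residues: list[Residue] = []
    for res in selected:
        hetfield, resseq, icode = res.id
        resname = res.get_resname().strip().upper()
        if hetfield.strip() and resname not in MODIFIED_TO_ONE:
            continue  # water / ligand
        atoms: dict[str, np.ndarray] = {}
        for atom in res:
            # Disordered atoms proxy their highest-occupancy conformer.
            atoms[atom.get_name()] = np.array(atom.get_coord(), dtype=float)
        if not atoms:
            continue
        residues.append(
            Residue(
                seq_index=len(residues) + 1,
                aa=_resolve_aa(resname),
                atoms=atoms,
                orig_id=(selected.id, resseq, icode),
            )
        )

    if not residues:
        raise EmptyStructureError(f"zero parsable residues in {path}")
    return ProteinModel(
        model_id=model_id or path.rsplit("/", 1)[-1].removesuffix(".pdb"),
        residues=residues,
        source_path=path,
    )


def extract_sequence(model: ProteinModel) -> str:
    """Length-L one-letter amino-acid string of the model."""
    if len(model) == 0:
        raise InputError("empty model has no sequence")
    return "".join(res.aa for res in model.residues)


def check_completeness(model: ProteinModel, target_sequence: str) -> CompletenessReport:
    """Compare a model against its target sequence.

    A model is complete iff it has exactly one residue per target position,
    the one-letter codes match position-wise, and every residue carries a CA
    atom. When the model is shorter, missing target positions are located by
    greedy alignment of the model sequence into the target sequence.
    """
    if not target_sequence:
        raise InputError("target sequence is empty")
    target = target_sequence.upper()
    seq = extract_sequence(model)
    report = CompletenessReport(
        complete=True, model_length=len(seq), target_length=len(target)
    )

    if len(seq) == len(target):
        report.mismatches = {
            i + 1 for i, (a, b) in enumerate(zip(seq, target)) if a != b
        }
    else:
        # Greedy left-to-right placement of model residues onto the target.
        mi = 0
        for ti, t_aa in enumerate(target):
            if mi < len(seq) and seq[mi] == t_aa:
                mi += 1
            else:
                report.missing.add(ti + 1)
        if mi < len(seq):  # leftover model residues never matched
            report.mismatches.update(range(mi + 1, len(seq) + 1))

    report.missing_ca = {
        res.seq_index for res in model.residues if not res.has_atom("CA")
    }
    report.complete = not (report.missing or report.mismatches or report.missing_ca)
    return report
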
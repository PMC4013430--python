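"""Amino-acid constants shared across modules.

The internal column order for one-hot and profile features is alphabetical
by one-letter code; every file-format order (e.g. the PSI-BLAST PSSM column
order) is mapped onto it at read time.
"""

# Internal, frozen feature-column order.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

# Column order of the PSI-BLAST ASCII PSSM log-odds block.
PSSM_FILE_ORDER = "ARNDCQEGHILKMFPSTWYV"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"

# Common modified residues seen in predicted models / PDB entries.
# Anything not listed here and not standard resolves to 'X'.
MODIFIED_TO_ONE = {
    "MSE": "M",  # selenomethionine
    "SEC": "C",
    "PYL": "K",
    "HYP": "P",
    "SEP": "S",
    "TPO": "T",
    "PTR": "Y",
    "CSO": "C",
    "CME": "C",
    "MLY": "K",
    "M3L": "K",
    "KCX": "K",
}

# Theoretical maximum accessible surface areas (Å^2), Tien et al. (2013),
# used to normalise per-residue SASA into relative accessibility.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "X": 197.0,
}
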
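"""Amino-acid code tables shared across modules."""

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def one_letter(resname: str) -> str:
    """1-letter code for a 3-letter residue name ('X' if unknown)."""
    return THREE_TO_ONE.get(resname.upper(), "X")


def three_letter(code: str) -> str:
    return ONE_TO_THREE.get(code.upper(), "UNK")
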
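"""Bundled amino-acid property tables.

All tables are keyed by one-letter code over the 20 canonical amino acids.
``AA_ORDER`` fixes the component order of every 20-dimensional feature vector
in the package (alphabetical one-letter order).
"""

from __future__ import annotations

AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

AA_THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA_ONE_TO_THREE: dict[str, str] = {v: k for k, v in AA_THREE_TO_ONE.items()}

# Kyte & Doolittle hydropathy scale (default hydrophobicity scale; configurable
# at the feature-config level).
HYDROPHOBICITY_KD: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Residue volumes in cubic angstroms (Zamyatnin).
VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Formal side-chain charge at pH 7 (His treated as neutral here, but it is a
# member of the charged class below and a salt-bridge donor).
CHARGE: dict[str, int] = {
    **{aa: 0 for aa in AA_ORDER},
    "D": -1, "E": -1, "K": +1, "R": +1,
}

# Three-class physicochemical grouping: non-polar, polar, charged.
CLASS_NONPOLAR = frozenset("ACFGILMPVW")
CLASS_POLAR = frozenset("NQSTY")
CLASS_CHARGED = frozenset("DEHKR")
AA_CLASSES: dict[str, frozenset[str]] = {
    "nonpolar": CLASS_NONPOLAR,
    "polar": CLASS_POLAR,
    "charged": CLASS_CHARGED,
}
CLASS_ORDER = ("nonpolar", "polar", "charged")


def aa_class(aa: str) -> str:
    """Return the three-class group (nonpolar/polar/charged) of a residue."""
    for name, members in AA_CLASSES.items():
        if aa in members:
            return name
    raise KeyError(f"not a canonical amino acid: {aa!r}")


# Maximum attainable solvent-accessible surface area per residue type, in
# square angstroms (theoretical Gly-X-Gly values of Tien et al. 2013). The
# choice of normalization table is a configuration constant.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Van der Waals radii by element, in angstroms, for SASA computation.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90,
}
VDW_DEFAULT = 1.70

# Grantham (1974) amino-acid distance matrix (upper triangle; symmetric,
# zero diagonal). Combines composition, polarity and molecular volume.
_GRANTHAM_UPPER: dict[tuple[str, str], int] = {
    ("S", "R"): 110, ("S", "L"): 145, ("S", "P"): 74, ("S", "T"): 58,
    ("S", "A"): 99, ("S", "V"): 124, ("S", "G"): 56, ("S", "I"): 142,
    ("S", "F"): 155, ("S", "Y"): 144, ("S", "C"): 112, ("S", "H"): 89,
    ("S", "Q"): 68, ("S", "N"): 46, ("S", "K"): 121, ("S", "D"): 65,
    ("S", "E"): 80, ("S", "M"): 135, ("S", "W"): 177,
    ("R", "L"): 102, ("R", "P"): 103, ("R", "T"): 71, ("R", "A"): 112,
    ("R", "V"): 96, ("R", "G"): 125, ("R", "I"): 97, ("R", "F"): 97,
    ("R", "Y"): 77, ("R", "C"): 180, ("R", "H"): 29, ("R", "Q"): 43,
    ("R", "N"): 86, ("R", "K"): 26, ("R", "D"): 96, ("R", "E"): 54,
    ("R", "M"): 91, ("R", "W"): 101,
    ("L", "P"): 98, ("L", "T"): 92, ("L", "A"): 96, ("L", "V"): 32,
    ("L", "G"): 138, ("L", "I"): 5, ("L", "F"): 22, ("L", "Y"): 36,
    ("L", "C"): 198, ("L", "H"): 99, ("L", "Q"): 113, ("L", "N"): 153,
    ("L", "K"): 107, ("L", "D"): 172, ("L", "E"): 138, ("L", "M"): 15,
    ("L", "W"): 61,
    ("P", "T"): 38, ("P", "A"): 27, ("P", "V"): 68, ("P", "G"): 42,
    ("P", "I"): 95, ("P", "F"): 114, ("P", "Y"): 110, ("P", "C"): 169,
    ("P", "H"): 77, ("P", "Q"): 76, ("P", "N"): 91, ("P", "K"): 103,
    ("P", "D"): 108, ("P", "E"): 93, ("P", "M"): 87, ("P", "W"): 147,
    ("T", "A"): 58, ("T", "V"): 69, ("T", "G"): 59, ("T", "I"): 89,
    ("T", "F"): 103, ("T", "Y"): 92, ("T", "C"): 149, ("T", "H"): 47,
    ("T", "Q"): 42, ("T", "N"): 65, ("T", "K"): 78, ("T", "D"): 85,
    ("T", "E"): 65, ("T", "M"): 81, ("T", "W"): 128,
    ("A", "V"): 64, ("A", "G"): 60, ("A", "I"): 94, ("A", "F"): 113,
    ("A", "Y"): 112, ("A", "C"): 195, ("A", "H"): 86, ("A", "Q"): 91,
    ("A", "N"): 111, ("A", "K"): 106, ("A", "D"): 126, ("A", "E"): 107,
    ("A", "M"): 84, ("A", "W"): 148,
    ("V", "G"): 109, ("V", "I"): 29, ("V", "F"): 50, ("V", "Y"): 55,
    ("V", "C"): 192, ("V", "H"): 84, ("V", "Q"): 96, ("V", "N"): 133,
    ("V", "K"): 97, ("V", "D"): 152, ("V", "E"): 121, ("V", "M"): 21,
    ("V", "W"): 88,
    ("G", "I"): 135, ("G", "F"): 153, ("G", "Y"): 147, ("G", "C"): 159,
    ("G", "H"): 98, ("G", "Q"): 87, ("G", "N"): 80, ("G", "K"): 127,
    ("G", "D"): 94, ("G", "E"): 98, ("G", "M"): 127, ("G", "W"): 184,
    ("I", "F"): 21, ("I", "Y"): 33, ("I", "C"): 198, ("I", "H"): 94,
    ("I", "Q"): 109, ("I", "N"): 149, ("I", "K"): 102, ("I", "D"): 168,
    ("I", "E"): 134, ("I", "M"): 10, ("I", "W"): 61,
    ("F", "Y"): 22, ("F", "C"): 205, ("F", "H"): 100, ("F", "Q"): 116,
    ("F", "N"): 158, ("F", "K"): 102, ("F", "D"): 177, ("F", "E"): 140,
    ("F", "M"): 28, ("F", "W"): 40,
    ("Y", "C"): 194, ("Y", "H"): 83, ("Y", "Q"): 99, ("Y", "N"): 143,
    ("Y", "K"): 85, ("Y", "D"): 160, ("Y", "E"): 122, ("Y", "M"): 36,
    ("Y", "W"): 37,
    ("C", "H"): 174, ("C", "Q"): 154, ("C", "N"): 139, ("C", "K"): 202,
    ("C", "D"): 154, ("C", "E"): 170, ("C", "M"): 196, ("C", "W"): 215,
    ("H", "Q"): 24, ("H", "N"): 68, ("H", "K"): 32, ("H", "D"): 81,
    ("H", "E"): 40, ("H", "M"): 87, ("H", "W"): 115,
    ("Q", "N"): 46, ("Q", "K"): 53, ("Q", "D"): 61, ("Q", "E"): 29,
    ("Q", "M"): 101, ("Q", "W"): 130,
    ("N", "K"): 94, ("N", "D"): 23, ("N", "E"): 42, ("N", "M"): 142,
    ("N", "W"): 174,
    ("K", "D"): 101, ("K", "E"): 56, ("K", "M"): 95, ("K", "W"): 110,
    ("D", "E"): 45, ("D", "M"): 160, ("D", "W"): 181,
    ("E", "M"): 126, ("E", "W"): 152,
    ("M", "W"): 67,
}


def grantham(wt: str, mut: str) -> int:
    """Grantham chemical dissimilarity between two amino acids (0 for identity)."""
    if wt not in AA_ONE_TO_THREE or mut not in AA_ONE_TO_THREE:
        raise KeyError(f"not canonical amino acids: {wt!r}, {mut!r}")
    if wt == mut:
        return 0
    key = (wt, mut) if (wt, mut) in _GRANTHAM_UPPER else (mut, wt)
    return _GRANTHAM_UPPER[key]


GRANTHAM: dict[tuple[str, str], int] = {
    **{(a, b): v for (a, b), v in _GRANTHAM_UPPER.items()},
    **{(b, a): v for (a, b), v in _GRANTHAM_UPPER.items()},
    **{(a, a): 0 for a in AA_ORDER},
}
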
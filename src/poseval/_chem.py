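"""Shared chemical reference data: radii tables and residue codes.

Van der Waals radii are Bondi's consensus set (Å) with Rowland/Taylor's
update for H; covalent radii follow Cordero et al. single-bond values.
Both tables are frozen here so every check in the toolkit is reproducible
independent of library versions.
"""

from __future__ import annotations

# Bondi (1964) van der Waals radii, Å.  Fallback 2.0 for exotic elements.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "B": 1.92, "SI": 2.10, "SE": 1.90,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
    "FE": 1.95, "MN": 1.95, "CU": 1.40, "NI": 1.63, "CO": 1.95,
}
VDW_DEFAULT = 2.0

# Cordero et al. (2008) single-bond covalent radii, Å.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "B": 0.84, "SI": 1.11, "SE": 1.20,
    "NA": 1.66, "K": 2.03, "MG": 1.41, "CA": 1.76, "ZN": 1.22,
    "FE": 1.32, "MN": 1.39, "CU": 1.32, "NI": 1.24, "CO": 1.26,
}
COVALENT_DEFAULT = 1.5

METALS = frozenset({
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA",
    "MN", "FE", "CO", "NI", "CU", "ZN", "CD", "HG",
})

HALOGENS = frozenset({"CL", "BR", "I"})

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), VDW_DEFAULT)


def covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(element.upper(), COVALENT_DEFAULT)
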
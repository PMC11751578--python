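"""Ideal internal-coordinate tables for the 20 standard amino acids.

These constants drive three things and must stay mutually consistent:

* the synthetic generator builds side chains from ``SIDECHAIN_ZMATRIX``;
* ``CHI_ATOMS`` defines which dihedrals are the chi angles;
* the stereochemistry check derives its bonded topology (and the ideal
  values it compares against) from the same Z-matrix entries, so an
  unperturbed synthetic structure is violation-free by construction.

Bond lengths are in Angstrom, angles and torsions in degrees.  Values are a
single standard ideal-geometry set (Engh/Huber-style averages rounded to
typical force-field precision); they are repo constants, not fit to data.

Each Z-matrix row reads ``(atom, (a, b, c), bond, angle, torsion)``: the new
atom is bonded to ``c`` at distance ``bond``, with angle ``b-c-atom`` and
dihedral ``a-b-c-atom``.  ``torsion`` is either a number (fixed, degrees) or
``("chi", k, offset)`` meaning chi_k + offset.  Ring-closure bonds (e.g. PRO
CD-N, aromatic ring closure) are intentionally absent from the bonded
topology derived here; rings are built to close by consistent ideal angles.
"""
from __future__ import annotations

# ---------------------------------------------------------------- residues

STANDARD_AA = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Fixed mapping for common modified residues; anything absent is dropped.
NONSTANDARD_MAP = {
    "MSE": "MET",  # selenomethionine (SE -> SD)
    "SEC": "CYS",
    "CSO": "CYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "MLY": "LYS",
    "HYP": "PRO",
}
# atom renames applied together with NONSTANDARD_MAP
NONSTANDARD_ATOM_RENAME = {"MSE": {"SE": "SD"}}

# ---------------------------------------------------------------- backbone

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# peptide-unit ideal geometry
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# CB ideal placement: bond CA-CB, angle N-CA-CB, improper dihedral C-N-CA-CB
BOND_CA_CB = 1.530
ANGLE_N_CA_CB = 110.4
IMPROPER_C_N_CA_CB = 122.7  # sign gives L-amino-acid chirality (checked in tests)
# PRO needs a tighter N-CA-CB to close its pyrrolidine ring exactly at the
# pucker chis below (CD-N comes out at 1.473 A)
ANGLE_N_CA_CB_BY_RES = {"PRO": 102.0}

# preset backbone torsions (phi, psi); omega = 180 throughout
PRESET_TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
}

# --------------------------------------------------------- side-chain chis

CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# chi angles whose terminal group is 2-fold symmetric: chi and chi+180 are
# the same physical state.  ASN/GLN/HIS flips are chemically distinguishable
# and deliberately NOT listed.
CHI_SYMMETRIC: set[tuple[str, int]] = {("ASP", 2), ("GLU", 3), ("PHE", 2), ("TYR", 2)}

# atom-name pairs that are swapped by the 2-fold symmetry above (plus ARG NH),
# used for ambiguous-naming resolution in distance-based scoring
AMBIGUOUS_ATOM_SWAPS: dict[str, list[tuple[str, str]]] = {
    "ASP": [("OD1", "OD2")],
    "GLU": [("OE1", "OE2")],
    "PHE": [("CD1", "CD2"), ("CE1", "CE2")],
    "TYR": [("CD1", "CD2"), ("CE1", "CE2")],
    "ARG": [("NH1", "NH2")],
}

# ------------------------------------------------------ side-chain Z-matrix

Chi = tuple  # ("chi", index, offset)


def _chi(k: int, offset: float = 0.0) -> Chi:
    return ("chi", k, offset)


SIDECHAIN_ZMATRIX: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, _chi(1))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 113.8, _chi(1))],
    "THR": [("OG1", ("N", "CA", "CB"), 1.433, 109.5, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0))],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.527, 110.4, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.527, 110.4, _chi(1, 120.0))],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0)),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.9, _chi(2))],
    "LEU": [("CG", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2, 120.0))],
    "ASP": [("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0))],
    "ASN": [("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0))],
    "GLU": [("CG", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3)),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3, 180.0))],
    "GLN": [("CG", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0))],
    "MET": [("CG", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("SD", ("CA", "CB", "CG"), 1.807, 112.7, _chi(2)),
            ("CE", ("CB", "CG", "SD"), 1.789, 100.8, _chi(3))],
    "LYS": [("CG", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.523, 111.3, _chi(2)),
            ("CE", ("CB", "CG", "CD"), 1.523, 111.3, _chi(3)),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, _chi(4))],
    "ARG": [("CG", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.523, 111.3, _chi(2)),
            ("NE", ("CB", "CG", "CD"), 1.461, 112.0, _chi(3)),
            ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, _chi(4)),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "HIS": [("CG", ("N", "CA", "CB"), 1.504, 113.8, _chi(1)),
            ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.354, 131.2, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.321, 109.0, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0)],
    "PHE": [("CG", ("N", "CA", "CB"), 1.509, 113.8, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.391, 120.7, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.391, 120.7, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.392, 120.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.392, 120.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.391, 120.0, 0.0)],
    "TYR": [("CG", ("N", "CA", "CB"), 1.511, 113.8, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.391, 120.7, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.391, 120.7, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.392, 120.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.392, 120.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.391, 120.0, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.377, 119.9, 180.0)],
    "TRP": [("CG", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.363, 126.9, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.432, 126.8, _chi(2, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.375, 110.2, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
            ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
            ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
            ("CH2", ("CE3", "CZ3", "CZ2"), 1.368, 117.5, 0.0)],
    "PRO": [("CG", ("N", "CA", "CB"), 1.495, 104.5, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.507, 106.1, _chi(2))],
}

# TRP CH2 closes the six-ring between CZ2 and CZ3; its Z-matrix row references
# CZ2 only through the frame (a) atom, the bond is to CZ3 via parent order
# (CE3, CZ3, CZ2) -> bonded atom is CZ2.  Bond list derivation uses parent c.

# one fixed chi set per residue type (a single common rotamer; mimics a
# "predefined conformation" side-chain baseline)
IDEAL_SINGLE_CHI: dict[str, tuple[float, ...]] = {
    "ALA": (), "GLY": (),
    "SER": (-65.0,), "CYS": (-65.0,), "THR": (-60.0,), "VAL": (175.0,),
    "ILE": (-65.0, 170.0), "LEU": (-65.0, 175.0),
    "ASP": (-70.0, -15.0), "ASN": (-65.0, -40.0),
    "GLU": (-67.0, -178.0, -10.0), "GLN": (-67.0, 180.0, -25.0),
    "MET": (-65.0, -65.0, -70.0),
    "LYS": (-67.0, 180.0, 180.0, 180.0), "ARG": (-67.0, 180.0, 180.0, 180.0),
    "HIS": (-65.0, -70.0), "PHE": (-65.0, 90.0), "TYR": (-65.0, 90.0),
    "TRP": (-65.0, 95.0), "PRO": (-19.5, 36.0),
}

# discrete chi library for the random_library rotamer mode
ROTAMER_LIBRARY_CHI1 = (-65.0, 180.0, 65.0)
ROTAMER_LIBRARY_CHI = (-65.0, 180.0, 65.0)
ROTAMER_LIBRARY_RING_CHI2 = (90.0, -90.0)
RING_CHI2_RESIDUES = {"PHE", "TYR", "TRP", "HIS"}

# standard-deviation scales used by the stereochemistry check
STEREO_BOND_SIGMA = 0.02   # Angstrom
STEREO_ANGLE_SIGMA = 2.5   # degrees
CLASH_FLOOR = 1.5          # Angstrom, heavy atoms of different residues


def element_of(atom_name: str) -> str:
    """Element symbol from a (heavy-atom) PDB atom name."""
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def sidechain_atom_names(resname: str) -> list[str]:
    """Heavy side-chain atom names beyond CB for a standard residue."""
    return [row[0] for row in SIDECHAIN_ZMATRIX.get(resname, [])]


def n_chi(resname: str) -> int:
    return len(CHI_ATOMS.get(resname, []))
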
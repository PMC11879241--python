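"""Amino-acid chemistry tables and idealized side-chain construction.

One place for the per-residue facts every energy term consumes: canonical
heavy-atom lists, internal-coordinate build rules for idealized side chains,
H-bond donor/acceptor atoms, aromatic-ring membership, charged-group atoms
and the solvation atom classes.

Side chains are built with the standard three-reference (NeRF) placement:
each atom is positioned from a bond length, a bond angle and a torsion
relative to three previously placed atoms.  Torsions are either fixed
(ring geometry, planar groups) or tied to a chi angle.
"""

from __future__ import annotations

import math

import numpy as np

AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3_TO_1 = {v: k for k, v in AA1_TO_3.items()}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# ---------------------------------------------------------------------------
# geometry kernel: three-reference atom placement
# ---------------------------------------------------------------------------


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D bonded to ``c`` given chain a-b-c.

    ``bond`` = |c-D|, ``angle_deg`` = angle(b, c, D),
    ``torsion_deg`` = dihedral(a, b, c, D).
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ValueError("collinear reference atoms in placement")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# side-chain build rules
# ---------------------------------------------------------------------------

# rule = (atom, (a, b, c), bond, angle, torsion); torsion is a float or
# ("chi", k, offset) meaning chi_k + offset.  CB is shared by all non-Gly.
_CB = ("CB", ("N", "C", "CA"), 1.530, 110.1, 122.5)

Tors = float | tuple
Rule = tuple[str, tuple[str, str, str], float, float, Tors]

SIDECHAIN_RULES: dict[str, list[Rule]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [
        _CB,
        ("OG1", ("N", "CA", "CB"), 1.433, 109.5, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 122.0)),
    ],
    "LEU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 122.0)),
    ],
    "ILE": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "MET": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.8, ("chi", 3, 0.0)),
    ],
    "PRO": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.490, 104.5, 30.0),
        ("CD", ("CA", "CB", "CG"), 1.500, 105.5, -35.0),
    ],
    "PHE": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.500, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.390, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.390, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.390, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.390, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0),
    ],
    "TYR": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.500, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.390, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.390, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.390, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.390, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.380, 119.9, 180.0),
    ],
    "TRP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.500, 113.6, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.433, 126.7, ("chi", 2, 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
        ("CE2", ("CG", "CD1", "NE1"), 1.370, 109.0, 0.0),
        ("CE3", ("CD1", "CG", "CD2"), 1.400, 133.9, 180.0),
        ("CZ2", ("CD1", "NE1", "CE2"), 1.390, 130.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.390, 118.8, 180.0),
        ("CH2", ("CD2", "CE3", "CZ3"), 1.370, 121.2, 0.0),
    ],
    "ASP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 113.0, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.250, 118.5, ("chi", 2, 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.250, 118.5, ("chi", 2, 180.0)),
    ],
    "ASN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 113.0, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 113.9, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.250, 118.5, ("chi", 3, 0.0)),
        ("OE2", ("CB", "CG", "CD"), 1.250, 118.5, ("chi", 3, 180.0)),
    ],
    "GLN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 113.9, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 3, 180.0)),
    ],
    "LYS": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 113.9, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.520, 111.3, ("chi", 3, 0.0)),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, ("chi", 4, 0.0)),
    ],
    "ARG": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 113.9, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("NE", ("CB", "CG", "CD"), 1.461, 112.0, ("chi", 3, 0.0)),
        ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, ("chi", 4, 0.0)),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
    "HIS": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.500, 113.8, ("chi", 1, 0.0)),
        ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.354, 131.0, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.320, 109.0, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0),
    ],
}

N_CHI = {
    "GLY": 0, "ALA": 0, "PRO": 0,
    "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "LEU": 2, "ILE": 2, "PHE": 2, "TYR": 2, "TRP": 2,
    "ASP": 2, "ASN": 2, "HIS": 2,
    "MET": 3, "GLU": 3, "GLN": 3,
    "LYS": 4, "ARG": 4,
}

SIDECHAIN_ATOMS = {
    aa: [r[0] for r in rules] for aa, rules in SIDECHAIN_RULES.items()
}

# ---------------------------------------------------------------------------
# H-bond donors / acceptors (heavy atoms); backbone handled separately
# ---------------------------------------------------------------------------

SIDECHAIN_DONORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "ASN": ["ND2"], "GLN": ["NE2"],
    "LYS": ["NZ"], "ARG": ["NE", "NH1", "NH2"],
    "HIS": ["ND1", "NE2"], "TRP": ["NE1"],
}

SIDECHAIN_ACCEPTORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "ASN": ["OD1"], "GLN": ["OE1"],
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"],
    "HIS": ["ND1", "NE2"],
}

#: donors/acceptors that form charged (salt-bridge class) H-bonds
CHARGED_DONOR_ATOMS = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
CHARGED_ACCEPTOR_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}

# ---------------------------------------------------------------------------
# aromatic rings and pi groups
# ---------------------------------------------------------------------------

RING_ATOMS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "TRP": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
}

GUANIDINIUM_ATOMS = ["CZ", "NE", "NH1", "NH2"]

# ---------------------------------------------------------------------------
# ionizable groups
# ---------------------------------------------------------------------------

#: atoms whose centroid is the point-charge site, and the ionized charge
CHARGE_SITES = {
    "ASP": (["OD1", "OD2"], -1),
    "GLU": (["OE1", "OE2"], -1),
    "CYS": (["SG"], -1),
    "TYR": (["OH"], -1),
    "HIS": (["ND1", "NE2"], +1),
    "LYS": (["NZ"], +1),
    "ARG": (["NE", "NH1", "NH2", "CZ"], +1),
}

ACIDIC_KINDS = {"ASP", "GLU", "CYS", "TYR", "CTER"}
BASIC_KINDS = {"HIS", "LYS", "ARG", "NTER"}

# ---------------------------------------------------------------------------
# solvation atom classes
# ---------------------------------------------------------------------------

_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CHARGED_N = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}


def atom_class(aa: str, name: str) -> str:
    """Solvation class of a heavy atom (see the shipped parameter file)."""
    if name == "N":
        return "backbone_N"
    if name in ("O", "OXT"):
        return "backbone_O"
    if name in ("CA", "C"):
        return "backbone_C"
    if (aa, name) in _CHARGED_O:
        return "charged_O"
    if (aa, name) in _CHARGED_N:
        return "charged_N"
    element = name[0] if name[0] in "CNOS" else name[1]
    if element == "S":
        return "sulfur"
    if element == "O":
        return "polar_O"
    if element == "N":
        return "polar_N"
    if aa in RING_ATOMS and name in RING_ATOMS[aa]:
        return "aromatic_C"
    return "apolar_C"


def element_of(name: str) -> str:
    """Element symbol guessed from a PDB heavy-atom name."""
    for ch in name:
        if ch.isalpha():
            return ch if ch in "CNOSH" else "C"
    return "C"


# ---------------------------------------------------------------------------
# side-chain construction
# ---------------------------------------------------------------------------


def build_side_chain(backbone: dict[str, np.ndarray], aa: str,
                     chis: tuple[float, ...] = ()) -> dict[str, np.ndarray]:
    """Idealized side-chain heavy atoms for ``aa`` on the given backbone.

    ``backbone`` must contain N, CA and C positions.  ``chis`` supplies the
    chi torsions in degrees; missing ones default to 180 (trans).
    """
    if aa not in SIDECHAIN_RULES:
        raise ValueError(f"unknown residue type {aa!r}")
    pos = {k: np.asarray(v, dtype=float) for k, v in backbone.items()}
    nchi = N_CHI[aa]
    chi_full = [180.0] * nchi
    for k, val in enumerate(chis[:nchi]):
        chi_full[k] = float(val)
    out: dict[str, np.ndarray] = {}
    for name, (a, b, c), bond, angle, tors in SIDECHAIN_RULES[aa]:
        if isinstance(tors, tuple):
            _, k, offset = tors
            torsion = chi_full[k - 1] + offset
        else:
            torsion = tors
        p = place_atom(pos[a], pos[b], pos[c], bond, angle, torsion)
        pos[name] = p
        out[name] = p
    return out
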
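"""Hydrogen-bond detection, geometric weighting and special cases.

A candidate donor-acceptor pair (heavy atoms within 3.5 Angstrom) is scored
from three angles measured on the proton and free-orbital dummy sites:

* ``freeProtDon`` -- at the proton, between proton->orbital and proton->donor,
* ``protFreeAcc`` -- at the orbital, between orbital->proton and
  orbital->acceptor,
* ``dihed``       -- the donor-proton-orbital-acceptor dihedral.

Each angle carries a trapezoidal weight: 1 inside the optimal window,
a linear ramp between min..optMin and optMax..max, 0 outside the hard
window (the pair is then not an H-bond at all).  The dihedral weight is 1
at the class's optimal dihedral, falling linearly to 0 at a deviation equal
to the optimum itself.  The bond energy is the base energy times the product
of the three weights; boundaries are class-specific (backbone-backbone,
backbone-side-chain, side-chain-side-chain).

Special cases implemented here: the delocalized Arg-carboxylate double salt
bridge (FRONT/SIDE patterns, energy x1.5 from v2 on) and the helix Ncap
bonus (base 1.32 kcal/mol, x1.5 for Ser/Asn and x2 for Thr from v4 on).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .params import ForceField, HBondGeometryTable, get_params
from .residues import CHARGED_ACCEPTOR_ATOMS, CHARGED_DONOR_ATOMS
from .structure import (
    Atom,
    DummyKind,
    DummySite,
    HelixAnnotation,
    Residue,
    Structure,
    angle_deg,
    dihedral_angle,
)

logger = logging.getLogger("ddgforge")

NCAP_DONOR_OXYGENS = {
    "SER": ["OG"], "THR": ["OG1"], "ASN": ["OD1"], "ASP": ["OD1", "OD2"],
}
NCAP_HBOND_CUTOFF = 3.5


class SaltBridgeMode(str, Enum):
    NONE = "NONE"
    FRONT = "FRONT"
    SIDE = "SIDE"


@dataclass
class HBond:
    donor: Atom
    acceptor: Atom
    proton: DummySite
    orbital: DummySite
    klass: str
    freeProtDon: float
    protFreeAcc: float
    dihed: float
    geometry_weight: float
    energy: float


def window_weight(x: float, lo: float, opt_lo: float, opt_hi: float,
                  hi: float) -> float:
    """Trapezoid: 0 outside [lo, hi], 1 inside [opt_lo, opt_hi], linear ramp."""
    if x < lo or x > hi:
        return 0.0
    if opt_lo <= x <= opt_hi:
        return 1.0
    if x < opt_lo:
        return (x - lo) / (opt_lo - lo) if opt_lo > lo else 1.0
    return (hi - x) / (hi - opt_hi) if hi > opt_hi else 1.0


def dihedral_weight(dihed: float, opt: float) -> float:
    """1 at |dihed| = opt, linear to 0 at a deviation of opt degrees."""
    if opt <= 0:
        return 1.0
    return max(0.0, 1.0 - abs(abs(dihed) - opt) / opt)


def classify_pair(donor: Atom, acceptor: Atom) -> str:
    if donor.is_backbone and acceptor.is_backbone:
        return "BB-BB"
    if donor.is_backbone or acceptor.is_backbone:
        return "BB-SC"
    return "SC-SC"


def is_charged_pair(donor: Atom, acceptor: Atom) -> bool:
    dkey = (donor.residue.aa_type, donor.name)
    akey = (acceptor.residue.aa_type, acceptor.name)
    return dkey in CHARGED_DONOR_ATOMS and akey in CHARGED_ACCEPTOR_ATOMS


def _score_pair(donor: Atom, acceptor: Atom, protons: list[DummySite],
                orbitals: list[DummySite], table: HBondGeometryTable,
                ) -> tuple[float, DummySite, DummySite, float, float, float] | None:
    """Best (weight, proton, orbital, angles...) over the dummy candidates."""
    klass = classify_pair(donor, acceptor)
    tbl = table.for_class(klass)
    best = None
    for proton in protons:
        for orbital in orbitals:
            if np.linalg.norm(proton.position - orbital.position) < 1e-6:
                continue
            fpd = angle_deg(orbital.position, proton.position, donor.position)
            pfa = angle_deg(proton.position, orbital.position,
                            acceptor.position)
            w1 = window_weight(fpd, tbl["minFreeProtDon"],
                               tbl["optMinFreeProtDon"],
                               tbl["optMaxFreeProtDon"],
                               tbl["maxFreeProtDon"])
            w2 = window_weight(pfa, tbl["minProtFreeAcc"],
                               tbl["optMinProtFreeAcc"],
                               tbl["optMaxProtFreeAcc"],
                               tbl["maxProtFreeAcc"])
            if w1 == 0.0 or w2 == 0.0:
                continue
            try:
                dih = dihedral_angle(donor.position, proton.position,
                                     orbital.position, acceptor.position)
            except ValueError:
                continue
            w3 = dihedral_weight(dih, tbl["optDihed"])
            w = w1 * w2 * w3
            if best is None or w > best[0]:
                best = (w, proton, orbital, fpd, pfa, dih)
    return best


def detect_and_score_hbonds(s: Structure, table: HBondGeometryTable,
                            base_energy: float = -1.32,
                            charged_energy: float | None = None,
                            ) -> list[HBond]:
    """All accepted H-bonds of an annotated structure.

    ``base_energy`` applies to neutral bonds; pairs between charged groups
    (Lys/Arg/His nitrogens donating to carboxylate oxygens) use
    ``charged_energy`` when given.
    """
    if not s.annotated:
        raise ValueError("structure must be annotated before H-bond detection")
    protons_by_atom: dict[int, list[DummySite]] = {}
    orbitals_by_atom: dict[int, list[DummySite]] = {}
    for d in s.dummy_sites:
        if d.kind is DummyKind.PROTON:
            protons_by_atom.setdefault(id(d.parent_atom), []).append(d)
        elif d.kind is DummyKind.FREE_ORBITAL:
            orbitals_by_atom.setdefault(id(d.parent_atom), []).append(d)

    donors = [a for a in s.atoms() if id(a) in protons_by_atom]
    acceptors = [a for a in s.atoms() if id(a) in orbitals_by_atom]
    cutoff = 3.5
    out: list[HBond] = []
    for donor in donors:
        for acceptor in acceptors:
            if donor.residue is acceptor.residue:
                continue
            d = float(np.linalg.norm(donor.position - acceptor.position))
            if d > cutoff or d < 2.0:
                continue
            best = _score_pair(donor, acceptor, protons_by_atom[id(donor)],
                               orbitals_by_atom[id(acceptor)], table)
            if best is None or best[0] <= 0.0:
                continue
            w, proton, orbital, fpd, pfa, dih = best
            base = base_energy
            if charged_energy is not None and is_charged_pair(donor, acceptor):
                base = charged_energy
            out.append(HBond(
                donor=donor, acceptor=acceptor, proton=proton,
                orbital=orbital, klass=classify_pair(donor, acceptor),
                freeProtDon=fpd, protFreeAcc=pfa, dihed=dih,
                geometry_weight=w, energy=base * w,
            ))
    return out


# ---------------------------------------------------------------------------
# double salt bridge
# ---------------------------------------------------------------------------

_ARG_NITROGENS = ("NE", "NH1", "NH2")


def _carboxylate_oxygens(res: Residue) -> list[str]:
    if res.aa_type == "ASP":
        return ["OD1", "OD2"]
    if res.aa_type == "GLU":
        return ["OE1", "OE2"]
    # C-terminal carboxylate
    names = [n for n in ("O", "OXT") if res.atom(n) is not None]
    if len(names) == 2:
        return names
    return []


def double_salt_bridge(arg: Residue, carboxylate: Residue,
                       hbonds: list[HBond],
                       params: ForceField | None = None,
                       ) -> tuple[SaltBridgeMode, float]:
    """Classify the Arg-carboxylate H-bond network and return its factor.

    FRONT: both NH1 and NH2 donate to both carboxylate oxygens (the fully
    delocalized, twofold-symmetric pattern).  SIDE: a one-sided network with
    at least two N-O bonds.  The factor multiplies the participating charged
    H-bond energies (1.5 from v2 on; 1.0 in v1).
    """
    if arg.aa_type != "ARG":
        raise ValueError(f"expected ARG, got {arg.aa_type}")
    oxygens = _carboxylate_oxygens(carboxylate)
    if not oxygens:
        raise ValueError(
            f"{carboxylate.aa_type} has no carboxylate group"
        )
    if params is None:
        params = get_params("v10")

    bonds = [hb for hb in hbonds
             if hb.donor.residue is arg and hb.donor.name in _ARG_NITROGENS
             and hb.acceptor.residue is carboxylate
             and hb.acceptor.name in oxygens]
    donors = {hb.donor.name for hb in bonds}
    accs = {hb.acceptor.name for hb in bonds}
    if not bonds:
        return SaltBridgeMode.NONE, 1.0
    if {"NH1", "NH2"} <= donors and set(oxygens) <= accs:
        mode = SaltBridgeMode.FRONT
    elif len(bonds) >= 2:
        mode = SaltBridgeMode.SIDE
    else:
        return SaltBridgeMode.NONE, 1.0
    return mode, params.salt_bridge_factor


def salt_bridge_partners(s: Structure, hbonds: list[HBond],
                         params: ForceField,
                         ) -> list[tuple[Residue, Residue, SaltBridgeMode, float]]:
    """All Arg-carboxylate pairs of the structure with a double-bridge mode."""
    out = []
    for arg in s.residues():
        if arg.aa_type != "ARG":
            continue
        for other in s.residues():
            if other.aa_type not in ("ASP", "GLU"):
                continue
            mode, factor = double_salt_bridge(arg, other, hbonds, params)
            if mode is not SaltBridgeMode.NONE:
                out.append((arg, other, mode, factor))
    return out


# ---------------------------------------------------------------------------
# Ncap bonus
# ---------------------------------------------------------------------------


def ncap_bonus(helix: HelixAnnotation, s: Structure,
               params: ForceField | None = None) -> float:
    """Helix N-capping bonus, kcal/mol (0 when no capping bond exists).

    The Ncap residue is the one preceding the first helical residue.  If it
    is Ser/Thr/Asn/Asp and a side-chain oxygen hydrogen-bonds the backbone
    amide of the third helical residue (Ncap+3), the bonus is the 1.32
    kcal/mol H-bond contribution scaled by the residue multiplier
    (Ser/Asn 1.5, Thr 2.0 from v4 on; 1.0 before, and always for Asp).
    """
    if params is None:
        params = get_params("v10")
    chain = s.chains.get(helix.chain_id, [])
    members = [r for r in chain
               if helix.start_seq <= r.seq_number <= helix.end_seq]
    if len(members) < 4:
        logger.warning("helix %s%d-%d too short for an Ncap",
                       helix.chain_id, helix.start_seq, helix.end_seq)
        return 0.0
    first_idx = chain.index(members[0])
    if first_idx == 0:
        return 0.0
    ncap = chain[first_idx - 1]
    if ncap.aa_type not in NCAP_DONOR_OXYGENS:
        return 0.0
    target = members[2]  # Ncap+3 counting the Ncap itself as position 0
    n_atom = target.atom("N")
    if n_atom is None:
        return 0.0
    bonded = False
    for name in NCAP_DONOR_OXYGENS[ncap.aa_type]:
        o_atom = ncap.atom(name)
        if o_atom is None:
            continue
        if np.linalg.norm(o_atom.position - n_atom.position) <= NCAP_HBOND_CUTOFF:
            bonded = True
            break
    if not bonded:
        return 0.0
    mult = params.ncap_multipliers.get(ncap.aa_type, 1.0)
    return -params.hbond["ncap_base"] * mult
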
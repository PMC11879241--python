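"""Charge-charge and charge-helix-dipole electrostatics with pH dependence.

Charged groups are represented by a point charge at the centroid of their
terminal heavy atoms, weighted by the degree of ionization at the working
pH.  The screened Coulomb form used throughout is

    E = k * q1 * q2 * exp(-d / lambda_D) / (eps * d^p)

with k = 332.0637 kcal*Angstrom/(mol*e^2), an effective relative
permittivity ``eps``, a Debye length lambda_D = 3.04/sqrt(I) Angstrom, and
p = 1 for charge-charge terms.  Charge-to-helix-dipole interactions use
p = 2 from v3 on; the first public release divided by the plain distance,
which is retained as the v1/v2 behaviour for regression comparisons.

Intrinsic pKas (His 6.8 and Cys 8.5 fixed; a standard experimental
compilation for the rest) are shifted by the electrostatic environment:
interactions stabilizing the ionized form push the pKa toward ionization
(down for acids, up for bases) by dG/(2.303 RT).  The degree of ionization
then follows Henderson-Hasselbalch, and burying an ionized group costs
P*(1-sigma) where sigma is the fractional solvent accessibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import ForceField, get_params
from .residues import ACIDIC_KINDS, CHARGE_SITES
from .structure import DummyKind, Residue, Structure

R_KCAL = 1.987204e-3  # kcal/(mol*K)


@dataclass
class PHContext:
    ph: float = 7.0
    temperature: float = 298.0     # Kelvin
    ionic_strength: float = 0.05   # molar

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"pH {self.ph} outside [0, 14]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class IonizableGroup:
    residue: Residue | None
    kind: str                      # ASP/GLU/LYS/ARG/TYR/HIS/CYS/NTER/CTER
    position: np.ndarray
    intrinsic_pka: float
    charge_when_ionized: int
    corrected_pka: float = 0.0
    ionization_fraction: float = 0.0
    accessibility: float = 1.0
    burial_atom: object = field(default=None, repr=False)

    @property
    def is_acid(self) -> bool:
        return self.kind in ACIDIC_KINDS


def coulomb_energy(q1: float, q2: float, d: float, ctx: PHContext,
                   dipole_mode: bool = False,
                   params: ForceField | None = None) -> float:
    """Screened Coulomb energy (kcal/mol) between charges ``q1``/``q2`` (e)."""
    if d <= 0:
        raise ValueError("distance must be positive")
    if q1 == 0.0 or q2 == 0.0:
        return 0.0
    if params is None:
        params = get_params("v10")
    el = params.electrostatics
    power = params.dipole_distance_power if dipole_mode else 1
    lam = el["debye_factor"] / math.sqrt(max(ctx.ionic_strength, 1e-6))
    screen = math.exp(-d / lam)
    return el["coulomb_constant"] * q1 * q2 * screen / (el["dielectric"] * d ** power)


def ionization_fraction(pka: float, ctx: PHContext, is_acid: bool) -> float:
    """Henderson-Hasselbalch degree of ionization in [0, 1]."""
    if is_acid:
        return 1.0 / (1.0 + 10.0 ** (pka - ctx.ph))
    return 1.0 / (1.0 + 10.0 ** (ctx.ph - pka))


def ionization_cost(group: IonizableGroup, accessibility: float,
                    ctx: PHContext, params: ForceField | None = None) -> float:
    """Burial penalty for carrying the ionized charge, kcal/mol.

    Linear in (1 - accessibility): zero for a fully exposed group, the full
    penalty constant for a completely buried one.
    """
    if not 0.0 <= accessibility <= 1.0:
        raise ValueError(f"accessibility {accessibility} outside [0, 1]")
    if params is None:
        params = get_params("v10")
    return params.electrostatics["ionization_penalty"] * (1.0 - accessibility)


def find_ionizable_groups(s: Structure, params: ForceField,
                          include_termini: bool = True,
                          ) -> list[IonizableGroup]:
    """Enumerate ionizable side chains (and chain termini) with their
    intrinsic pKas and charge sites."""
    pkas = params.electrostatics["intrinsic_pka"]
    groups: list[IonizableGroup] = []
    for res in s.residues():
        if res.aa_type not in CHARGE_SITES or res.aa_type not in pkas:
            continue
        if not params.ph_all_residues and res.aa_type not in ("HIS", "CYS"):
            continue
        names, charge = CHARGE_SITES[res.aa_type]
        atoms = [res.atom(n) for n in names]
        atoms = [a for a in atoms if a is not None]
        if not atoms:
            continue
        pos = np.mean([a.position for a in atoms], axis=0)
        groups.append(IonizableGroup(
            residue=res, kind=res.aa_type, position=pos,
            intrinsic_pka=float(pkas[res.aa_type]),
            charge_when_ionized=charge, burial_atom=atoms[0]))
    if include_termini and params.ph_all_residues:
        for chain in s.chains.values():
            if not chain:
                continue
            n = chain[0].atom("N")
            if n is not None and "NTER" in pkas:
                groups.append(IonizableGroup(
                    residue=chain[0], kind="NTER", position=n.position.copy(),
                    intrinsic_pka=float(pkas["NTER"]),
                    charge_when_ionized=+1, burial_atom=n))
            names = [nm for nm in ("O", "OXT") if chain[-1].atom(nm)]
            if len(names) == 2 and "CTER" in pkas:
                pos = np.mean([chain[-1].atom(nm).position for nm in names],
                              axis=0)
                groups.append(IonizableGroup(
                    residue=chain[-1], kind="CTER", position=pos,
                    intrinsic_pka=float(pkas["CTER"]),
                    charge_when_ionized=-1,
                    burial_atom=chain[-1].atom("OXT")))
    return groups


def corrected_pka(group: IonizableGroup, s: Structure, ctx: PHContext,
                  params: ForceField | None = None,
                  groups: list[IonizableGroup] | None = None) -> float:
    """Environment-corrected pKa of one ionizable group.

    The electrostatic energy of the ionized form against every other group
    (full formal charges, within the neighbour cutoff) is converted to a pKa
    shift of dG/(2.303 RT); stabilizing interactions favour ionization.
    """
    if params is None:
        params = get_params("v10")
    if groups is None:
        groups = find_ionizable_groups(s, params)
    cutoff = params.electrostatics["pka_neighbour_cutoff"]
    dg = 0.0
    for other in groups:
        if other is group or (other.residue is group.residue
                              and other.kind == group.kind):
            continue
        d = float(np.linalg.norm(group.position - other.position))
        if d < 1e-6 or d > cutoff:
            continue
        dg += coulomb_energy(group.charge_when_ionized,
                             other.charge_when_ionized, d, ctx, params=params)
    shift = dg / (2.302585 * R_KCAL * ctx.temperature)
    if group.is_acid:
        return group.intrinsic_pka + shift
    return group.intrinsic_pka - shift


def ionize_structure(s: Structure, ctx: PHContext, params: ForceField,
                     accessibility_fn=None) -> list[IonizableGroup]:
    """Resolve every ionizable group's corrected pKa and ionization state."""
    groups = find_ionizable_groups(s, params)
    for g in groups:
        g.corrected_pka = corrected_pka(g, s, ctx, params, groups)
        g.ionization_fraction = ionization_fraction(g.corrected_pka, ctx,
                                                    g.is_acid)
        if accessibility_fn is not None and g.burial_atom is not None:
            g.accessibility = float(accessibility_fn(g.burial_atom))
    return groups


def charge_charge_energy(s: Structure, ctx: PHContext, params: ForceField,
                         groups: list[IonizableGroup] | None = None) -> float:
    """Pairwise ionized-group electrostatics plus ionization burial costs."""
    if groups is None:
        groups = ionize_structure(s, ctx, params)
    total = 0.0
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            d = float(np.linalg.norm(g1.position - g2.position))
            if d < 1e-6:
                continue
            total += coulomb_energy(
                g1.charge_when_ionized * g1.ionization_fraction,
                g2.charge_when_ionized * g2.ionization_fraction,
                d, ctx, params=params)
        total += g1.ionization_fraction * ionization_cost(
            g1, g1.accessibility, ctx, params)
    return total


def helix_dipole_energy(s: Structure, ctx: PHContext,
                        params: ForceField | None = None,
                        groups: list[IonizableGroup] | None = None) -> float:
    """Interaction of ionized groups with the helix-cap dipole dummies."""
    if params is None:
        params = get_params("v10")
    if not s.annotated:
        raise ValueError("structure must be annotated")
    caps = [d for d in s.dummy_sites
            if d.kind in (DummyKind.NCAP_DIPOLE, DummyKind.CCAP_DIPOLE)]
    if not caps:
        return 0.0
    if groups is None:
        groups = ionize_structure(s, ctx, params)
    total = 0.0
    for cap in caps:
        for g in groups:
            d = float(np.linalg.norm(cap.position - g.position))
            if d < 1e-6:
                continue
            total += coulomb_energy(
                cap.charge, g.charge_when_ionized * g.ionization_fraction,
                d, ctx, dipole_mode=True, params=params)
    return total
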
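"""Buried-volume occupancy model, per-atom solvation and side-chain entropy.

Burial of an atom is the occluded volume contributed by its neighbours,

    B_i = sum_j V_j * (1 - d_ij / cutoff)   for d_ij < cutoff (6 Angstrom),

mapped to a fractional burial through per-atom minimum and maximum buried
volumes: fraction = clamp((B - min) / (max - min), 0, 1).  From v9 on,
aromatic ring atoms count with 0.9 of their volume (close ring packing
otherwise over-buries neighbours); v10 raises every minimum by 10 and the
proline ring minimums to the aromatic values.

Solvation energy is linear in the buried fraction with per-atom-class
hydrophobic/polar constants; from v7 on every apolar Trp side-chain atom
carries an extra -0.2 kcal/mol.  Side-chain conformational entropy is paid
proportionally to burial: cost = T * dS * burial, with the Met dS raised to
the Lys value (0.0073667) from v5 on.
"""

from __future__ import annotations

import numpy as np

from .params import ForceField, get_params
from .residues import RING_ATOMS, atom_class
from .structure import Atom, Residue, Structure


def is_ring_atom(aa: str, name: str) -> bool:
    return aa in RING_ATOMS and name in RING_ATOMS[aa]


def atom_volume(atom: Atom, params: ForceField) -> float:
    """Occluding volume of an atom, with the v9 ring-atom reduction."""
    vols = params.volumes["element_volume"]
    if atom.element not in vols:
        raise KeyError(f"no volume parameter for element {atom.element!r} "
                       f"(atom {atom.name})")
    v = float(vols[atom.element])
    if is_ring_atom(atom.residue.aa_type, atom.name):
        v *= params.ring_volume_factor
    return v


def min_max_buried(atom: Atom, params: ForceField) -> tuple[float, float]:
    """Per-atom minimum/maximum buried volumes for the active version."""
    vol = params.volumes
    aa = atom.residue.aa_type
    lo = float(vol["min_buried_default"])
    overrides = vol.get("min_buried_overrides", {})
    if aa in overrides and atom.name in overrides[aa]:
        lo = float(overrides[aa][atom.name])
    if params.pro_min_buried_v10:
        v10 = vol.get("v10_pro_overrides", {})
        if aa in v10 and atom.name in v10[aa]:
            lo = float(v10[aa][atom.name])
    lo += params.min_buried_extra
    hi = float(vol["max_buried_default"])
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def buried_volume(atom: Atom, s: Structure,
                  params: ForceField | None = None) -> float:
    """Occluded volume B_i from all neighbours within the kernel cutoff."""
    if params is None:
        params = get_params("v10")
    cutoff = params.volumes["occlusion_cutoff"]
    b = 0.0
    for other in s.atoms():
        if other is atom:
            continue
        d = float(np.linalg.norm(atom.position - other.position))
        if d >= cutoff:
            continue
        b += atom_volume(other, params) * (1.0 - d / cutoff)
    return b


def buried_fraction(atom: Atom, s: Structure,
                    params: ForceField | None = None) -> float:
    """Fractional burial of an atom in [0, 1]."""
    if params is None:
        params = get_params("v10")
    b = buried_volume(atom, s, params)
    lo, hi = min_max_buried(atom, params)
    return float(np.clip((b - lo) / (hi - lo), 0.0, 1.0))


def solvation_energy(atom: Atom, fraction: float,
                     params: ForceField | None = None) -> float:
    """Desolvation energy of one atom at the given burial, kcal/mol."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if params is None:
        params = get_params("v10")
    res = atom.residue
    klass = atom_class(res.aa_type, atom.name)
    cls = params.solvation["classes"][klass]
    hydrophobic = float(cls["hydrophobic"])
    if (params.trp_apolar_shift != 0.0 and res.aa_type == "TRP"
            and not atom.is_backbone and atom.name != "NE1"):
        hydrophobic += params.trp_apolar_shift
    return fraction * (hydrophobic + float(cls["polar"]))


def residue_side_chain_burial(res: Residue, s: Structure,
                              params: ForceField) -> float:
    """Mean burial of a residue's side-chain heavy atoms (0 if none)."""
    side = [a for a in res.atoms if not a.is_backbone]
    if not side:
        return 0.0
    return float(np.mean([buried_fraction(a, s, params) for a in side]))


def side_chain_entropy(res: Residue, burial: float, temperature: float,
                       table: dict[str, float] | None = None,
                       params: ForceField | None = None) -> float:
    """Entropic cost of fixing a side chain, kcal/mol (grows with burial)."""
    if not 0.0 <= burial <= 1.0:
        raise ValueError(f"burial {burial} outside [0, 1]")
    if table is None:
        if params is None:
            params = get_params("v10")
        table = params.entropy_table
    ds = float(table.get(res.aa_type, 0.0))
    return temperature * ds * burial


def total_solvation_energy(s: Structure, params: ForceField) -> float:
    return sum(solvation_energy(a, buried_fraction(a, s, params), params)
               for a in s.atoms())


def total_entropy_energy(s: Structure, temperature: float,
                         params: ForceField) -> float:
    table = params.entropy_table
    total = 0.0
    for res in s.residues():
        burial = residue_side_chain_burial(res, s, params)
        total += side_chain_entropy(res, burial, temperature, table)
    return total
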
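"""Pi-pi stacking between aromatic rings, His rings and Arg guanidinium groups.

The interaction is evaluated between dummy centroids placed at the center of
each ring/guanidinium group, with a hard 5 Angstrom centroid-distance gate.
Pairs involving a His ring or a guanidinium group additionally require the
inter-plane angle to stay within 30 degrees of coplanar and are scaled by an
angle factor theta = cos^2(angle); purely aromatic pairs (Phe/Tyr/Trp) use
theta = 1.  The optimal magnitude is E_opt = 2.5 kcal/mol, reduced by 0.25
per Phe in the pair (0.5 when both are Phe), and corrected by a distance
factor f(d) that is 1 up to the optimal separation and falls off as a
Gaussian beyond it.  Stabilizing energies are returned negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .params import ForceField, get_params
from .residues import GUANIDINIUM_ATOMS, RING_ATOMS
from .structure import Residue, Structure, fit_plane

logger = logging.getLogger("ddgforge")

PI_KINDS = ("PHE", "TYR", "TRP", "HIS", "ARG_GUA")
_ANGLE_GATED = {"HIS", "ARG_GUA"}


@dataclass
class PiGroup:
    residue: Residue
    kind: str                 # PHE | TYR | TRP | HIS | ARG_GUA
    centroid: np.ndarray
    plane_normal: np.ndarray


def _group_from_atoms(res: Residue, kind: str, names: list[str],
                      ) -> PiGroup | None:
    atoms = [res.atom(n) for n in names]
    if any(a is None for a in atoms):
        logger.warning("%s %s%d incomplete; pi group omitted",
                       kind, res.chain_id, res.seq_number)
        return None
    pts = np.array([a.position for a in atoms])
    centroid, normal = fit_plane(pts)
    return PiGroup(residue=res, kind=kind, centroid=centroid,
                   plane_normal=normal)


def find_pi_groups(s: Structure) -> list[PiGroup]:
    """One pi group per aromatic/His ring and per Arg guanidinium group."""
    out: list[PiGroup] = []
    for res in s.residues():
        if res.aa_type in RING_ATOMS:
            g = _group_from_atoms(res, res.aa_type, RING_ATOMS[res.aa_type])
            if g is not None:
                out.append(g)
        elif res.aa_type == "ARG":
            g = _group_from_atoms(res, "ARG_GUA", GUANIDINIUM_ATOMS)
            if g is not None:
                out.append(g)
    return out


def pipi_energy(g1: PiGroup, g2: PiGroup,
                params: ForceField | None = None) -> float:
    """Stacking free energy of a pi-group pair, kcal/mol (<= 0)."""
    if g1.residue is g2.residue:
        raise ValueError("pi-pi energy requires two distinct residues")
    if params is None:
        params = get_params("v10")
    p = params.pipi
    d = float(np.linalg.norm(g1.centroid - g2.centroid))
    if d > p["distance_cutoff"]:
        return 0.0
    cosang = abs(float(np.dot(g1.plane_normal, g2.plane_normal)))
    cosang = min(1.0, cosang)
    angle = math.degrees(math.acos(cosang))
    gated = g1.kind in _ANGLE_GATED or g2.kind in _ANGLE_GATED
    if gated:
        if angle > p["angle_cutoff"]:
            return 0.0
        theta = cosang ** 2
    else:
        theta = 1.0
    n_phe = (g1.kind == "PHE") + (g2.kind == "PHE")
    e_opt = p["e_opt"] - p["phe_penalty"] * n_phe
    if d <= p["d_opt"]:
        f = 1.0
    else:
        f = math.exp(-((d - p["d_opt"]) ** 2) / (2.0 * p["sigma"] ** 2))
    return -e_opt * theta * f


def total_pipi_energy(s: Structure, params: ForceField | None = None) -> float:
    """Sum of pairwise stacking energies over all pi groups."""
    if params is None:
        params = get_params("v10")
    if not params.pipi_enabled:
        return 0.0
    groups = find_pi_groups(s)
    total = 0.0
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            if g1.residue is g2.residue:
                continue
            total += pipi_energy(g1, g2, params)
    return total
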
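"""Synthetic-structure and synthetic-benchmark generators.

Everything the test suite and the worked examples need is built here from
idealized internal coordinates: stacked ring pairs at an exact centroid
distance and inter-plane angle, ideal alpha-helical peptides with a chosen
N-capping residue, a delocalized Arg-carboxylate double salt bridge, and
noisy prediction/experiment benchmark tables with known generating
parameters.  All generators are deterministic given their arguments (and
seed, where randomness exists).
"""

from __future__ import annotations

import math

import numpy as np

from .curation import MutantRecord
from .residues import (
    AA3,
    GUANIDINIUM_ATOMS,
    N_CHI,
    RING_ATOMS,
    build_side_chain,
    element_of,
    place_atom,
)
from .structure import (
    Atom,
    HelixAnnotation,
    Residue,
    Structure,
    annotate_structure,
    fit_plane,
)

# ideal backbone internal coordinates (Angstrom / degrees)
BB_N_CA = 1.458
BB_CA_C = 1.525
BB_C_N = 1.329
BB_C_O = 1.231
ANG_C_N_CA = 121.7
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_CA_C_O = 120.8
HELIX_PHI = -57.0
HELIX_PSI = -47.0


def _residue_from_positions(aa: str, chain: str, seq: int,
                            positions: dict[str, np.ndarray]) -> Residue:
    res = Residue(aa_type=aa, chain_id=chain, seq_number=seq)
    for name, pos in positions.items():
        res.add_atom(Atom(name=name, element=element_of(name), position=pos))
    return res


def make_backbone(n: int, phi=HELIX_PHI, psi=HELIX_PSI,
                  ) -> list[dict[str, np.ndarray]]:
    """Ideal polypeptide backbone (N, CA, C, O per residue), single chain.

    ``phi``/``psi`` may be scalars or per-residue sequences (degrees).
    """
    phis = [float(p) for p in (phi if np.iterable(phi) else [phi] * n)]
    psis = [float(p) for p in (psi if np.iterable(psi) else [psi] * n)]
    if len(phis) != n or len(psis) != n:
        raise ValueError("phi/psi sequences must have length n")
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BB_N_CA, 0.0, 0.0])
    ang = math.radians(ANG_N_CA_C)
    c0 = ca0 + BB_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = res[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         BB_C_N, ANG_CA_C_N, psis[i - 1])
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          BB_N_CA, ANG_C_N_CA, 180.0)
        c_i = place_atom(prev["C"], n_i, ca_i, BB_CA_C, ANG_N_CA_C, phis[i])
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: trans to the next amide nitrogen
    for i, bb in enumerate(res):
        bb["O"] = place_atom(bb["N"], bb["CA"], bb["C"],
                             BB_C_O, ANG_CA_C_O, psis[i] + 180.0)
    return res


# ---------------------------------------------------------------------------
# ring pairs
# ---------------------------------------------------------------------------

_RING_KIND_TO_AA = {"PHE": "PHE", "TYR": "TYR", "TRP": "TRP", "HIS": "HIS",
                    "ARG_GUA": "ARG"}


def _build_residue(aa: str, chain: str, seq: int,
                   chis: tuple[float, ...] = ()) -> Residue:
    bb = make_backbone(1)[0]
    side = build_side_chain(bb, aa, chis)
    return _residue_from_positions(aa, chain, seq, {**bb, **side})


def _group_atoms(res: Residue) -> list[str]:
    if res.aa_type == "ARG":
        return GUANIDINIUM_ATOMS
    return RING_ATOMS[res.aa_type]


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return (np.eye(3) + math.sin(angle_rad) * k
            + (1 - math.cos(angle_rad)) * (k @ k))


def _transform_residue(res: Residue, rot: np.ndarray, about: np.ndarray,
                       shift: np.ndarray) -> None:
    for a in res.atoms:
        a.position = rot @ (a.position - about) + about + shift


def make_ring_pair(kind1: str, kind2: str, distance: float,
                   angle: float) -> Structure:
    """Two residues with their pi groups at an exact centroid separation
    and inter-plane angle (degrees), stacked along the first group's normal.
    """
    for kind in (kind1, kind2):
        if kind not in _RING_KIND_TO_AA:
            raise ValueError(f"unsupported pi-group kind {kind!r}")
    if distance < 2.0:
        raise ValueError("centroid distance below 2 Angstrom is unphysical")

    res1 = _build_residue(_RING_KIND_TO_AA[kind1], "A", 1)
    res2 = _build_residue(_RING_KIND_TO_AA[kind2], "A", 10)
    pts1 = np.array([res1.atom(n).position for n in _group_atoms(res1)])
    c1, n1 = fit_plane(pts1)
    pts2 = np.array([res2.atom(n).position for n in _group_atoms(res2)])
    c2, n2 = fit_plane(pts2)

    # align group-2 normal with group-1 normal ...
    cross = np.cross(n2, n1)
    dot = float(np.dot(n2, n1))
    if np.linalg.norm(cross) < 1e-9:
        rot_align = np.eye(3) if dot > 0 else _rotation_matrix(
            _perp_of(n1), math.pi)
    else:
        rot_align = _rotation_matrix(cross, math.atan2(np.linalg.norm(cross),
                                                       dot))
    _transform_residue(res2, rot_align, c2, np.zeros(3))
    # ... then tilt it by the requested angle about an in-plane axis
    tilt_axis = _perp_of(n1)
    _transform_residue(res2, _rotation_matrix(tilt_axis,
                                              math.radians(angle)),
                       c2, np.zeros(3))
    # place the centroid at the exact separation along n1 and pick the
    # azimuth that best separates the two backbones
    target = c1 + distance * n1
    best = None
    for az in range(0, 360, 30):
        rot = _rotation_matrix(n1, math.radians(az))
        probe = [rot @ (a.position - c2) + target for a in res2.atoms]
        dmin = min(np.linalg.norm(p - b.position)
                   for p in probe for b in res1.atoms)
        if best is None or dmin > best[0]:
            best = (dmin, rot)
    _transform_residue(res2, best[1], c2, target - c2)

    s = Structure()
    s.add_residue(res1)
    s.add_residue(res2)
    return annotate_structure(s)


def _perp_of(v: np.ndarray) -> np.ndarray:
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, v)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    w = probe - np.dot(probe, v) * v
    return w / np.linalg.norm(w)


# ---------------------------------------------------------------------------
# helix peptides
# ---------------------------------------------------------------------------


def make_helix_peptide(n: int, ncap_aa: str = "SER",
                       seq: list[str] | None = None) -> Structure:
    """Ideal alpha-helix of ``n`` residues whose first residue is the Ncap.

    Residues 2..n are annotated as the helix; the Ncap side chain (for
    Ser/Thr/Asn/Asp) is rotated to hydrogen-bond the backbone nitrogen of
    the third helical residue when geometrically possible.
    """
    if n < 6:
        raise ValueError("need at least 6 residues for a capped helix")
    if ncap_aa not in AA3:
        raise ValueError(f"invalid residue code {ncap_aa!r}")
    if seq is None:
        seq = ["ALA"] * n
    if len(seq) != n:
        raise ValueError("sequence length must equal n")
    seq = list(seq)
    seq[0] = ncap_aa

    # the capping residue takes the canonical extended Ncap conformation so
    # its side chain can point back over the helix face
    phis = [-95.0] + [HELIX_PHI] * (n - 1)
    psis = [160.0] + [HELIX_PSI] * (n - 1)
    backbone = make_backbone(n, phis, psis)
    s = Structure()
    residues = []
    for i, (aa, bb) in enumerate(zip(seq, backbone), start=1):
        side = build_side_chain(bb, aa, ())
        res = _residue_from_positions(aa, "A", i, {**bb, **side})
        residues.append(res)
        s.add_residue(res)
    s.helices = [HelixAnnotation("A", 2, n)]

    cap_oxygens = {"SER": "OG", "THR": "OG1", "ASN": "OD1", "ASP": "OD1"}
    if ncap_aa in cap_oxygens:
        _point_capping_oxygen(residues[0], cap_oxygens[ncap_aa],
                              residues[3].atom("N").position, backbone[0])
    return annotate_structure(s)


def _point_capping_oxygen(res: Residue, oxygen: str, target: np.ndarray,
                          bb: dict[str, np.ndarray]) -> None:
    """Scan chi angles to bring the capping oxygen ~2.9 A from the target N."""
    aa = res.aa_type
    nchi = N_CHI[aa]
    best = None
    grid1 = np.arange(0.0, 360.0, 2.0)
    grid2 = np.arange(0.0, 360.0, 10.0) if nchi >= 2 else [180.0]
    for chi1 in grid1:
        for chi2 in grid2:
            side = build_side_chain(bb, aa, (chi1, chi2))
            d = float(np.linalg.norm(side[oxygen] - target))
            score = abs(d - 2.9)
            if best is None or score < best[0]:
                best = (score, side)
    for name, pos in best[1].items():
        res.atom(name).position = pos


def make_helix_bundle(seq: list[str] | None = None,
                      n: int = 10,
                      spacing: float = 8.5) -> Structure:
    """Parallel five-helix cluster for burial-dependent terms.

    The same ideal helix is replicated on chains A-E around the central one
    at roughly coiled-coil packing distance, giving the central chain a
    range of genuinely buried atoms.
    """
    if seq is None:
        seq = (["ALA", "LEU", "PHE", "ALA", "LEU"] * ((n + 4) // 5))[:n]
    base = make_helix_peptide(n, ncap_aa=seq[0], seq=seq)
    half = spacing / 2.0
    ynear = spacing * 0.87
    offsets = [("A", (0.0, 0.0, 0.0)), ("B", (spacing, 0.0, 0.0)),
               ("C", (half, ynear, 0.0)), ("D", (-half, ynear, 0.0)),
               ("E", (-spacing, 0.0, 0.0))]
    out = Structure()
    for cid, off in offsets:
        shift = np.array(off)
        for r in base.residues():
            nr = Residue(r.aa_type, cid, r.seq_number)
            for a in r.atoms:
                nr.add_atom(Atom(a.name, a.element, a.position + shift))
            out.add_residue(nr)
        out.helices.append(HelixAnnotation(cid, 2, n))
    return annotate_structure(out)


# ---------------------------------------------------------------------------
# double salt bridge
# ---------------------------------------------------------------------------


def make_salt_bridge(n_o_distance: float = 2.85) -> Structure:
    """Coplanar FRONT Arg-Asp double salt bridge fixture.

    Guanidinium and carboxylate groups face each other in one plane with
    both NH nitrogens at ``n_o_distance`` from both-side carboxylate
    oxygens' H-bond geometry; the backbones trail away on either side.
    """
    cz = np.array([0.0, 0.0, 0.0])
    ne = np.array([-1.33, 0.0, 0.0])
    nh1 = 1.326 * np.array([math.cos(math.radians(60)),
                            math.sin(math.radians(60)), 0.0])
    nh2 = nh1 * np.array([1.0, -1.0, 1.0])
    # carboxylate carbon on the symmetry axis; oxygens mirror the NH pair
    half = math.radians(62.0)
    cg_x = nh1[0] + n_o_distance + 1.25 * math.cos(half)
    od1 = np.array([cg_x - 1.25 * math.cos(half), 1.25 * math.sin(half), 0.0])
    od2 = od1 * np.array([1.0, -1.0, 1.0])
    cg_d = np.array([cg_x, 0.0, 0.0])

    arg_pos = {"CZ": cz, "NE": ne, "NH1": nh1, "NH2": nh2}
    arg_pos["CD"] = place_atom(nh1, cz, ne, 1.46, 124.0, 180.0)
    arg_pos["CG"] = place_atom(cz, ne, arg_pos["CD"], 1.52, 112.0, 90.0)
    arg_pos["CB"] = place_atom(ne, arg_pos["CD"], arg_pos["CG"],
                               1.52, 111.0, 180.0)
    arg_pos["CA"] = place_atom(arg_pos["CD"], arg_pos["CG"], arg_pos["CB"],
                               1.52, 111.0, 180.0)
    arg_pos["N"] = place_atom(arg_pos["CG"], arg_pos["CB"], arg_pos["CA"],
                              1.458, 110.0, -60.0)
    arg_pos["C"] = place_atom(arg_pos["N"], arg_pos["CB"], arg_pos["CA"],
                              1.525, 111.0, -122.5)
    arg_pos["O"] = place_atom(arg_pos["CB"], arg_pos["CA"], arg_pos["C"],
                              1.231, 120.8, 60.0)

    asp_pos = {"CG": cg_d, "OD1": od1, "OD2": od2}
    asp_pos["CB"] = place_atom(od1, od2, cg_d, 1.52, 118.0, 180.0)
    asp_pos["CA"] = place_atom(od2, cg_d, asp_pos["CB"], 1.52, 113.0, 120.0)
    asp_pos["N"] = place_atom(cg_d, asp_pos["CB"], asp_pos["CA"],
                              1.458, 110.0, -60.0)
    asp_pos["C"] = place_atom(asp_pos["N"], asp_pos["CB"], asp_pos["CA"],
                              1.525, 111.0, -122.5)
    asp_pos["O"] = place_atom(asp_pos["CB"], asp_pos["CA"], asp_pos["C"],
                              1.231, 120.8, 60.0)

    s = Structure()
    s.add_residue(_residue_from_positions("ARG", "A", 1, arg_pos))
    s.add_residue(_residue_from_positions("ASP", "A", 10, asp_pos))
    return annotate_structure(s)


# ---------------------------------------------------------------------------
# benchmark tables
# ---------------------------------------------------------------------------


def make_benchmark_table(n: int, slope: float = 1.0, intercept: float = 0.0,
                         noise_sd: float = 1.0, seed: int = 0,
                         ) -> tuple[list[MutantRecord], np.ndarray]:
    """Synthetic benchmark: predictions plus noisy linked experimental ddGs.

    Latent predicted ddGs are drawn from N(1.0, 1.5^2) kcal/mol (the rough
    location/spread of curated stability benchmarks) and the experimental
    values generated as ``slope * pred + intercept + N(0, noise_sd)``, so a
    regression of experiment on prediction recovers the generating slope
    and intercept exactly in the noiseless case.
    """
    if n < 10:
        raise ValueError("need at least 10 records")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    pred = rng.normal(1.0, 1.5, size=n)
    exp = slope * pred + intercept + rng.normal(0.0, noise_sd, size=n)
    aa_codes = [a for a in AA3 if a != "GLY"]
    records = []
    for i in range(n):
        wt, mut = rng.choice(len(aa_codes), size=2, replace=False)
        records.append(MutantRecord(
            pdb_id=f"SYN{i:04d}", chain="A",
            wt_aa=aa_codes[wt][0], seq_number=int(10 + i),
            mut_aa=aa_codes[mut][0], ddg_exp=float(exp[i]),
            temperature=25.0, ph=7.0, method="XRAY", resolution=1.5,
        ))
    return records, pred


def noise_for_population_r(slope: float, target_r: float,
                           pred_sd: float = 1.5) -> float:
    """Noise s.d. giving a population Pearson R for the benchmark generator."""
    if not 0 < target_r < 1:
        raise ValueError("target R must be in (0, 1)")
    return abs(slope) * pred_sd * math.sqrt(1.0 / target_r ** 2 - 1.0)
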
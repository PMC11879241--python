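"""Typed structure model, PDB I/O, dummy interaction sites, geometry kernels.

The model is a plain chain/residue/atom hierarchy carrying the metadata the
curation filters need (resolution, experimental method) plus the non-atomic
interaction sites the force field works with:

* protons and acceptor lone-pair ("free orbital") dummies for H-bond
  geometry,
* ring and guanidinium centroids for pi-pi stacking,
* helix-cap dipole charges of +0.5 / -0.5 e placed at the centroid of the
  first four amide nitrogens and the last four carbonyl oxygens of a helix.

Reading and writing PDB files is delegated to gemmi; hydrogens in the input
are discarded (protons are always rebuilt as dummies from ideal covalent
geometry).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import gemmi
import numpy as np

from .residues import (
    AA3,
    BACKBONE_ATOMS,
    GUANIDINIUM_ATOMS,
    RING_ATOMS,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    element_of,
)

logger = logging.getLogger("ddgforge")

PROTON_LENGTH = 1.00    # Angstrom, N/O-H
ORBITAL_LENGTH = 1.00   # Angstrom, acceptor lone-pair dummy
BOND_CUTOFF = 1.85      # Angstrom, covalent-bond detection
BOND_CUTOFF_S = 2.10    # Angstrom, bonds involving sulfur
HELIX_HBOND_CUTOFF = 3.5  # Angstrom, O(i)..N(i+4) for helix fallback


class ParseError(ValueError):
    """Raised for malformed structure files."""


class ExperimentalMethod(str, Enum):
    XRAY = "XRAY"
    NMR = "NMR"
    EM = "EM"
    UNKNOWN = "UNKNOWN"


class DummyKind(str, Enum):
    PROTON = "PROTON"
    FREE_ORBITAL = "FREE_ORBITAL"
    RING_CENTROID = "RING_CENTROID"
    GUANIDINIUM_CENTROID = "GUANIDINIUM_CENTROID"
    NCAP_DIPOLE = "NCAP_DIPOLE"
    CCAP_DIPOLE = "CCAP_DIPOLE"


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    residue: "Residue | None" = field(default=None, repr=False)
    partial_charge: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class Residue:
    aa_type: str
    chain_id: str
    seq_number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.aa_type not in AA3:
            raise ValueError(f"non-canonical residue type {self.aa_type!r}")

    def add_atom(self, atom: Atom) -> None:
        if any(a.name == atom.name for a in self.atoms):
            raise ValueError(
                f"duplicate atom {atom.name} in {self.chain_id}{self.seq_number}"
            )
        atom.residue = self
        self.atoms.append(atom)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)


@dataclass
class HelixAnnotation:
    chain_id: str
    start_seq: int
    end_seq: int

    def __post_init__(self) -> None:
        if self.end_seq - self.start_seq < 3:
            raise ValueError("helix must span at least 4 residues")


@dataclass
class DummySite:
    kind: DummyKind
    position: np.ndarray
    charge: float = 0.0
    owner: object = None          # Residue or HelixAnnotation
    parent_atom: Atom | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Structure:
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    resolution: float | None = None
    experimental_method: ExperimentalMethod = ExperimentalMethod.UNKNOWN
    helices: list[HelixAnnotation] = field(default_factory=list)
    dummy_sites: list[DummySite] = field(default_factory=list)
    annotated: bool = False

    def add_residue(self, res: Residue) -> None:
        self.chains.setdefault(res.chain_id, []).append(res)

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def atoms(self):
        for res in self.residues():
            yield from res.atoms

    def get_residue(self, chain_id: str, seq_number: int) -> Residue | None:
        for res in self.chains.get(chain_id, []):
            if res.seq_number == seq_number:
                return res
        return None

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    # dummy lookups, filled by annotate_structure
    def protons_of(self, atom: Atom) -> list[DummySite]:
        return [d for d in self.dummy_sites
                if d.kind is DummyKind.PROTON and d.parent_atom is atom]

    def orbitals_of(self, atom: Atom) -> list[DummySite]:
        return [d for d in self.dummy_sites
                if d.kind is DummyKind.FREE_ORBITAL and d.parent_atom is atom]

    def copy(self) -> "Structure":
        out = Structure(
            resolution=self.resolution,
            experimental_method=self.experimental_method,
            helices=[HelixAnnotation(h.chain_id, h.start_seq, h.end_seq)
                     for h in self.helices],
        )
        for res in self.residues():
            new = Residue(res.aa_type, res.chain_id, res.seq_number,
                          res.insertion_code)
            for a in res.atoms:
                new.add_atom(Atom(a.name, a.element, a.position.copy(),
                                  partial_charge=a.partial_charge))
            out.add_residue(new)
        return out


# ---------------------------------------------------------------------------
# geometry kernels
# ---------------------------------------------------------------------------


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit plane of >=3 points: returns (centroid, unit normal)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit a plane")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8:
        raise ValueError("degenerate plane: points are collinear")
    return centroid, vt[2]


def plane_angle(group1: np.ndarray, group2: np.ndarray) -> float:
    """Angle between best-fit plane normals, folded to [0, 90] degrees."""
    _, n1 = fit_plane(group1)
    _, n2 = fit_plane(group2)
    cosang = abs(float(np.dot(n1, n2)))
    cosang = min(1.0, cosang)
    return math.degrees(math.acos(cosang))


def angle_deg(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle at ``p2`` of the triangle p1-p2-p3, degrees."""
    v1 = p1 - p2
    v2 = p3 - p2
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def dihedral_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                   d: np.ndarray) -> float:
    """Signed IUPAC dihedral of a-b-c-d in (-180, 180]."""
    b0 = np.asarray(b) - np.asarray(a)
    b1 = np.asarray(c) - np.asarray(b)
    b2 = np.asarray(d) - np.asarray(c)
    for v, lab in ((b0, "a-b"), (b1, "b-c"), (b2, "c-d")):
        if np.linalg.norm(v) < 1e-9:
            raise ValueError(f"coincident consecutive points ({lab})")
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def _prevalidate_pdb(path: str) -> None:
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n_atoms += 1
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}:{lineno}: truncated ATOM record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: malformed coordinates in ATOM record"
                    ) from None
    if n_atoms == 0:
        raise ParseError(f"{path}: no ATOM records found")


def read_structure(path: str) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Keeps the first altLoc and the lowest-numbered MODEL; hydrogens and
    non-canonical residues (waters, ligands) are dropped; HELIX records,
    REMARK 2 resolution and EXPDTA method are parsed when present.
    """
    _prevalidate_pdb(path)
    st = gemmi.read_structure(str(path))
    out = Structure()
    if st.resolution and st.resolution > 0:
        out.resolution = float(st.resolution)
    info = dict(st.info)
    method = info.get("_exptl.method", "") or ""
    method = method.upper()
    if "X-RAY" in method or "XRAY" in method:
        out.experimental_method = ExperimentalMethod.XRAY
    elif "NMR" in method:
        out.experimental_method = ExperimentalMethod.NMR
    elif "MICROSCOPY" in method or method == "EM":
        out.experimental_method = ExperimentalMethod.EM

    model = st[0]
    for chain in model:
        for res in chain:
            if res.name not in AA3:
                continue
            residue = Residue(
                aa_type=res.name,
                chain_id=chain.name,
                seq_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
            )
            for atom in res:
                if atom.element.name == "H" or atom.name.startswith("H"):
                    continue
                if atom.altloc not in ("", "\0", "A"):
                    continue
                if residue.atom(atom.name) is not None:
                    continue
                residue.add_atom(Atom(
                    name=atom.name,
                    element=atom.element.name or element_of(atom.name),
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                ))
            if residue.atoms:
                out.add_residue(residue)
    if out.n_atoms() == 0:
        raise ParseError(f"{path}: no canonical protein atoms found")

    for h in st.helices:
        try:
            ann = HelixAnnotation(
                chain_id=h.start.chain_name,
                start_seq=h.start.res_id.seqid.num,
                end_seq=h.end.res_id.seqid.num,
            )
        except ValueError:
            logger.warning("skipping helix record with <4 residues")
            continue
        out.helices.append(ann)
    return out


def write_structure(s: Structure, path: str) -> None:
    """Write standard 80-column PDB ATOM records (plus header metadata)."""
    lines = []
    if s.experimental_method is not ExperimentalMethod.UNKNOWN:
        name = {
            ExperimentalMethod.XRAY: "X-RAY DIFFRACTION",
            ExperimentalMethod.NMR: "SOLUTION NMR",
            ExperimentalMethod.EM: "ELECTRON MICROSCOPY",
        }[s.experimental_method]
        lines.append(f"EXPDTA    {name}".ljust(80))
    if s.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {s.resolution:7.2f} ANGSTROMS.".ljust(80)
        )
    for i, h in enumerate(s.helices, start=1):
        start = s.get_residue(h.chain_id, h.start_seq)
        end = s.get_residue(h.chain_id, h.end_seq)
        sname = start.aa_type if start else "ALA"
        ename = end.aa_type if end else "ALA"
        length = h.end_seq - h.start_seq + 1
        lines.append(
            f"HELIX  {i:3d} {i:3d} {sname} {h.chain_id}{h.start_seq:5d} "
            f"{ename} {h.chain_id}{h.end_seq:5d}  1{'':30}{length:6d}".ljust(80)
        )
    serial = 1
    for res in s.residues():
        for a in res.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {res.aa_type:<3s} "
                f"{res.chain_id}{res.seq_number:4d}{res.insertion_code or ' ':1s}"
                f"   {a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}".ljust(80)
            )
            serial += 1
    lines.append("END".ljust(80))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# bonding and dummy-site placement
# ---------------------------------------------------------------------------


def bonded_heavy_atoms(s: Structure, atom: Atom) -> list[Atom]:
    """Covalently bonded heavy atoms, by distance within the residue and to
    sequence-adjacent residues (peptide bonds)."""
    res = atom.residue
    chain = s.chains[res.chain_id]
    idx = chain.index(res)
    candidates = list(res.atoms)
    for j in (idx - 1, idx + 1):
        if 0 <= j < len(chain):
            candidates.extend(chain[j].atoms)
    out = []
    for other in candidates:
        if other is atom:
            continue
        cutoff = BOND_CUTOFF_S if "S" in (atom.element, other.element) \
            else BOND_CUTOFF
        if np.linalg.norm(atom.position - other.position) <= cutoff:
            out.append(other)
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("zero-length vector")
    return v / n


def _perp_component(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    w = v - np.dot(v, axis) * axis
    n = np.linalg.norm(w)
    if n < 1e-9:
        # arbitrary perpendicular
        probe = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(probe, axis)) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        w = probe - np.dot(probe, axis) * axis
        n = np.linalg.norm(w)
    return w / n


def _sp2_directions(atom: Atom, anchor: Atom, plane_ref: Atom,
                    theta_deg: float) -> list[np.ndarray]:
    """Two in-plane directions at ``theta`` off the anchor->atom axis."""
    u = _unit(atom.position - anchor.position)
    w = _perp_component(plane_ref.position - anchor.position, u)
    t = math.radians(theta_deg)
    return [math.cos(t) * u + math.sin(t) * w,
            math.cos(t) * u - math.sin(t) * w]


def _sp3_directions(atom: Atom, anchor: Atom, theta_deg: float,
                    n_azimuth: int = 3) -> list[np.ndarray]:
    """Cone of directions at ``theta`` off the anchor->atom axis."""
    u = _unit(atom.position - anchor.position)
    w1 = _perp_component(np.array([1.0, 0.3, -0.2]), u)
    w2 = np.cross(u, w1)
    t = math.radians(theta_deg)
    out = []
    for k in range(n_azimuth):
        phi = 2 * math.pi * k / n_azimuth
        out.append(math.cos(t) * u
                   + math.sin(t) * (math.cos(phi) * w1 + math.sin(phi) * w2))
    return out


def _outward_direction(atom: Atom, bonded: list[Atom]) -> np.ndarray:
    """Direction opposite the mean of the covalent-bond vectors."""
    acc = np.zeros(3)
    for b in bonded:
        acc += _unit(b.position - atom.position)
    return -_unit(acc)


_SP2_AMIDE = {("ASN", "ND2"), ("GLN", "NE2"), ("ARG", "NH1"), ("ARG", "NH2")}
_SP2_CARBONYL_ACC = {("ASN", "OD1"), ("GLN", "OE1"),
                     ("ASP", "OD1"), ("ASP", "OD2"),
                     ("GLU", "OE1"), ("GLU", "OE2")}
_HYDROXYL = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}


def _proton_directions(s: Structure, atom: Atom) -> list[np.ndarray]:
    aa = atom.residue.aa_type
    bonded = bonded_heavy_atoms(s, atom)
    if not bonded:
        return []
    key = (aa, atom.name)
    if atom.name == "N":  # backbone amide
        return [_outward_direction(atom, bonded)]
    if key in _SP2_AMIDE:
        anchor = bonded[0]
        others = bonded_heavy_atoms(s, anchor)
        ref = next((a for a in others if a is not atom), None)
        if ref is None:
            return [_outward_direction(atom, bonded)]
        return _sp2_directions(atom, anchor, ref, 60.0)
    if key in _HYDROXYL:
        return _sp3_directions(atom, bonded[0], 70.5)
    if key == ("LYS", "NZ"):
        return _sp3_directions(atom, bonded[0], 70.5)
    # ring NH (His, Trp), Arg NE: in-plane outward
    return [_outward_direction(atom, bonded)]


def _orbital_directions(s: Structure, atom: Atom) -> list[np.ndarray]:
    aa = atom.residue.aa_type
    bonded = bonded_heavy_atoms(s, atom)
    if not bonded:
        return []
    key = (aa, atom.name)
    if atom.name in ("O", "OXT") or key in _SP2_CARBONYL_ACC:
        anchor = bonded[0]
        others = bonded_heavy_atoms(s, anchor)
        ref = next((a for a in others if a is not atom), None)
        if ref is None:
            return [_outward_direction(atom, bonded)]
        dirs = _sp2_directions(atom, anchor, ref, 60.0)
        dirs.append(_unit(atom.position - anchor.position))
        return dirs
    if key in _HYDROXYL:
        return _sp3_directions(atom, bonded[0], 70.5)
    # ring N acceptors: in-plane outward lone pair
    return [_outward_direction(atom, bonded)]


def detect_helices_geometric(s: Structure) -> list[HelixAnnotation]:
    """Fallback helix detection from backbone O(i)..N(i+4) contacts."""
    out = []
    for chain_id, chain in s.chains.items():
        helical = [False] * len(chain)
        for i in range(len(chain) - 4):
            o = chain[i].atom("O")
            n = chain[i + 4].atom("N")
            if o is None or n is None:
                continue
            if chain[i + 4].seq_number - chain[i].seq_number != 4:
                continue
            if np.linalg.norm(o.position - n.position) <= HELIX_HBOND_CUTOFF:
                for j in range(i, i + 5):
                    helical[j] = True
        i = 0
        while i < len(chain):
            if helical[i]:
                j = i
                while j + 1 < len(chain) and helical[j + 1]:
                    j += 1
                if j - i + 1 >= 4:
                    out.append(HelixAnnotation(
                        chain_id, chain[i].seq_number, chain[j].seq_number))
                i = j + 1
            else:
                i += 1
    return out


def annotate_structure(s: Structure) -> Structure:
    """Place all dummy interaction sites on ``s`` (in place; returns ``s``).

    Adds helix-cap dipole charges, ring/guanidinium centroids and the
    proton / free-orbital dummies every H-bond candidate needs.  Helices are
    taken from the parsed records or detected geometrically when absent.
    """
    s.dummy_sites = []
    if not s.helices:
        s.helices = detect_helices_geometric(s)

    for helix in s.helices:
        chain = s.chains.get(helix.chain_id, [])
        members = [r for r in chain
                   if helix.start_seq <= r.seq_number <= helix.end_seq]
        if len(members) < 4:
            logger.warning("helix %s%d-%d has <4 residues; skipped",
                           helix.chain_id, helix.start_seq, helix.end_seq)
            continue
        n_atoms = [r.atom("N") for r in members[:4]]
        o_atoms = [r.atom("O") for r in members[-4:]]
        if all(a is not None for a in n_atoms):
            pos = np.mean([a.position for a in n_atoms], axis=0)
            s.dummy_sites.append(DummySite(DummyKind.NCAP_DIPOLE, pos,
                                           charge=+0.5, owner=helix))
        if all(a is not None for a in o_atoms):
            pos = np.mean([a.position for a in o_atoms], axis=0)
            s.dummy_sites.append(DummySite(DummyKind.CCAP_DIPOLE, pos,
                                           charge=-0.5, owner=helix))

    for res in s.residues():
        if res.aa_type in RING_ATOMS:
            atoms = [res.atom(n) for n in RING_ATOMS[res.aa_type]]
            if any(a is None for a in atoms):
                logger.warning("residue %s%d missing ring atoms; no centroid",
                               res.chain_id, res.seq_number)
            else:
                pos = np.mean([a.position for a in atoms], axis=0)
                s.dummy_sites.append(DummySite(DummyKind.RING_CENTROID, pos,
                                               owner=res))
        if res.aa_type == "ARG":
            atoms = [res.atom(n) for n in GUANIDINIUM_ATOMS]
            if any(a is None for a in atoms):
                logger.warning("Arg %s%d missing guanidinium atoms",
                               res.chain_id, res.seq_number)
            else:
                pos = np.mean([a.position for a in atoms], axis=0)
                s.dummy_sites.append(DummySite(
                    DummyKind.GUANIDINIUM_CENTROID, pos, owner=res))

        donors = []
        if res.aa_type != "PRO" and res.atom("N") is not None:
            donors.append(res.atom("N"))
        for name in SIDECHAIN_DONORS.get(res.aa_type, []):
            a = res.atom(name)
            if a is not None:
                donors.append(a)
        for atom in donors:
            try:
                dirs = _proton_directions(s, atom)
            except ValueError:
                dirs = []
            for d in dirs:
                s.dummy_sites.append(DummySite(
                    DummyKind.PROTON, atom.position + PROTON_LENGTH * d,
                    owner=res, parent_atom=atom))

        acceptors = []
        for name in ("O", "OXT"):
            a = res.atom(name)
            if a is not None:
                acceptors.append(a)
        for name in SIDECHAIN_ACCEPTORS.get(res.aa_type, []):
            a = res.atom(name)
            if a is not None:
                acceptors.append(a)
        for atom in acceptors:
            try:
                dirs = _orbital_directions(s, atom)
            except ValueError:
                dirs = []
            for d in dirs:
                s.dummy_sites.append(DummySite(
                    DummyKind.FREE_ORBITAL,
                    atom.position + ORBITAL_LENGTH * d,
                    owner=res, parent_atom=atom))

    s.annotated = True
    return s
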
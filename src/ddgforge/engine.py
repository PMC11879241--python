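"""Total-energy evaluation, point mutation and ddG with multi-run aggregation.

The engine follows a rigid-backbone philosophy: a mutation replaces one side
chain with idealized geometry and re-optimizes nearby side chains, but never
moves a backbone atom.  Side-chain placement is a seeded greedy search over
a 30-degree chi grid scored by local packing (soft-repulsion clashes plus a
polar-contact reward); repeated runs with different seeds explore different
tie-breaks, and ddG is the mean or median of ``n_runs`` paired
mutant-minus-wild-type evaluations (the wild type is rebuilt by the same
procedure so that a self-mutation gives exactly zero).

The clash term is a soft Lennard-Jones-like repulsion
``scale * ((r0/d)^12 - 1)`` summed over non-bonded heavy-atom pairs closer
than ``r0``; it also feeds the curation filter for structurally impossible
mutants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .electrostatics import (
    PHContext,
    charge_charge_energy,
    helix_dipole_energy,
    ionize_structure,
)
from .hbond import detect_and_score_hbonds, ncap_bonus, salt_bridge_partners
from .params import ForceField, get_params
from .pipi import total_pipi_energy
from .residues import AA1_TO_3, AA3, N_CHI, build_side_chain
from .solvation import (
    buried_fraction,
    total_entropy_energy,
    total_solvation_energy,
)
from .structure import Atom, Residue, Structure, annotate_structure

logger = logging.getLogger("ddgforge")

NEIGHBOUR_SHELL = 6.0   # Angstrom, side chains re-optimized around a mutation
CHI_GRID_STEP = 30.0    # degrees

TERMS = ("hbond", "electrostatics", "helix_dipole", "ncap", "pipi",
         "solvation", "entropy", "clash")


@dataclass
class Mutation:
    chain_id: str
    seq_number: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        self.wt_aa = _canonical_aa(self.wt_aa)
        self.mut_aa = _canonical_aa(self.mut_aa)

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        """Parse ``chain:WposM`` (e.g. ``A:T45W``) or ``W-chain-pos-M``."""
        text = text.strip().rstrip(";")
        if ":" in text:
            chain, rest = text.split(":", 1)
            return cls(chain, int(rest[1:-1]), rest[0], rest[-1])
        wt, chain, pos, mut = text.split("-")
        return cls(chain, int(pos), wt, mut)


def _canonical_aa(aa: str) -> str:
    aa = aa.upper()
    if len(aa) == 1:
        return AA1_TO_3[aa]
    if aa not in AA3:
        raise ValueError(f"unknown amino acid {aa!r}")
    return aa


@dataclass
class EnergyReport:
    terms: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))

    def to_dict(self) -> dict:
        out = {k: float(v) for k, v in self.terms.items()}
        out["total"] = self.total
        return out


# ---------------------------------------------------------------------------
# energy terms
# ---------------------------------------------------------------------------


def clash_energy(s: Structure, params: ForceField | None = None) -> float:
    """Soft repulsive penalty over non-bonded heavy-atom pairs, kcal/mol."""
    if params is None:
        params = get_params("v10")
    p = params.clash
    r0, scale, cap = p["r0"], p["scale"], p["pair_cap"]
    atoms = list(s.atoms())
    if len(atoms) < 2:
        return 0.0
    coords = np.array([a.position for a in atoms])
    tree = cKDTree(coords)
    total = 0.0
    for i, j in tree.query_pairs(r0):
        a, b = atoms[i], atoms[j]
        if _excluded_pair(s, a, b):
            continue
        d = float(np.linalg.norm(a.position - b.position))
        if d < 1e-3:
            d = 1e-3
        total += min(cap, scale * ((r0 / d) ** 12 - 1.0))
    return total


def _excluded_pair(s: Structure, a: Atom, b: Atom) -> bool:
    """Bonded or near-bonded pairs excluded from the clash sum."""
    ra, rb = a.residue, b.residue
    if ra is rb:
        return True
    if ra.chain_id == rb.chain_id:
        if abs(ra.seq_number - rb.seq_number) == 1:
            # peptide neighbours: backbone-backbone contacts are covalent
            # geometry, not clashes
            if a.is_backbone and b.is_backbone:
                return True
            if {"CB"} & {a.name, b.name} and (a.is_backbone or b.is_backbone):
                return True
    return False


def total_energy(s: Structure, ctx: PHContext | None = None,
                 params: ForceField | None = None) -> EnergyReport:
    """Per-term free-energy decomposition of an annotated structure."""
    if params is None:
        params = get_params("v10")
    if ctx is None:
        ctx = PHContext()
    if not s.annotated:
        raise ValueError("structure must be annotated (call annotate_structure)")

    report = EnergyReport(terms={t: 0.0 for t in TERMS})

    hb = params.hbond
    bonds = detect_and_score_hbonds(
        s, params.hbond_geometry,
        base_energy=hb["neutral_energy"],
        charged_energy=hb["charged_energy"])
    scaled = {id(b): b.energy for b in bonds}
    for arg, carbox, mode, factor in salt_bridge_partners(s, bonds, params):
        for b in bonds:
            if b.donor.residue is arg and b.acceptor.residue is carbox:
                scaled[id(b)] = b.energy * factor
    report.terms["hbond"] = float(sum(scaled.values()))

    def accessibility(atom):
        return 1.0 - buried_fraction(atom, s, params)

    groups = ionize_structure(s, ctx, params, accessibility_fn=accessibility)
    report.terms["electrostatics"] = charge_charge_energy(s, ctx, params,
                                                          groups)
    report.terms["helix_dipole"] = helix_dipole_energy(s, ctx, params, groups)
    report.terms["ncap"] = float(sum(ncap_bonus(h, s, params)
                                     for h in s.helices))
    report.terms["pipi"] = total_pipi_energy(s, params)
    report.terms["solvation"] = total_solvation_energy(s, params)
    report.terms["entropy"] = total_entropy_energy(s, ctx.temperature, params)
    report.terms["clash"] = clash_energy(s, params)
    return report


# ---------------------------------------------------------------------------
# side-chain placement
# ---------------------------------------------------------------------------


def _backbone_positions(res: Residue) -> dict[str, np.ndarray]:
    out = {}
    for name in ("N", "CA", "C"):
        a = res.atom(name)
        if a is None:
            raise ValueError(
                f"residue {res.chain_id}{res.seq_number} missing backbone {name}")
        out[name] = a.position
    return out


def _replace_side_chain(res: Residue, aa: str,
                        chis: tuple[float, ...]) -> None:
    bb_atoms = [a for a in res.atoms if a.is_backbone]
    side = build_side_chain(_backbone_positions(res), aa, chis)
    res.aa_type = aa
    res.atoms = bb_atoms
    for a in bb_atoms:
        a.residue = res
    for name, pos in side.items():
        res.add_atom(Atom(name=name, element=name[0] if name[0] in "CNOS"
                          else "C", position=pos))


_POLAR_ELEMENTS = {"N", "O"}


def _local_score(s: Structure, res: Residue, params: ForceField) -> float:
    """Fast packing score of one residue's side chain: soft clashes minus a
    small reward for polar contacts at H-bond range."""
    p = params.clash
    r0, scale, cap = p["r0"], p["scale"], p["pair_cap"]
    side = [a for a in res.atoms if not a.is_backbone]
    if not side:
        return 0.0
    score = 0.0
    for a in side:
        for b in s.atoms():
            if b.residue is res:
                continue
            if _excluded_pair(s, a, b):
                continue
            d = float(np.linalg.norm(a.position - b.position))
            if d < 1e-3:
                d = 1e-3
            if d < r0:
                score += min(cap, scale * ((r0 / d) ** 12 - 1.0))
            if (2.6 <= d <= 3.4 and a.element in _POLAR_ELEMENTS
                    and b.element in _POLAR_ELEMENTS):
                score -= 0.5
    return score


def _optimize_side_chain(s: Structure, res: Residue, rng: np.random.Generator,
                         params: ForceField) -> None:
    """Greedy seeded chi-grid search (30-degree steps, chi-by-chi)."""
    nchi = N_CHI[res.aa_type]
    if nchi == 0:
        return
    current = [180.0] * nchi
    grid = np.arange(0.0, 360.0, CHI_GRID_STEP)
    for k in range(nchi):
        options = list(grid)
        rng.shuffle(options)
        best_chi, best_score = None, None
        for chi in options:
            trial = list(current)
            trial[k] = float(chi)
            _replace_side_chain(res, res.aa_type, tuple(trial))
            score = _local_score(s, res, params)
            if best_score is None or score < best_score - 1e-9:
                best_chi, best_score = float(chi), score
        current[k] = best_chi
    _replace_side_chain(res, res.aa_type, tuple(current))


# ---------------------------------------------------------------------------
# mutate / repair / ddG
# ---------------------------------------------------------------------------


def mutate(s: Structure, m: Mutation, seed: int = 0,
           params: ForceField | None = None) -> Structure:
    """Point-mutate a structure; backbone coordinates are bit-identical.

    The target side chain is rebuilt in idealized geometry with a seeded
    chi-grid search, and side chains within 6 Angstrom of the mutated
    residue are re-optimized by the same search.
    """
    if params is None:
        params = get_params("v10")
    res = s.get_residue(m.chain_id, m.seq_number)
    if res is None:
        raise ValueError(f"no residue {m.chain_id}:{m.seq_number}")
    if res.aa_type != m.wt_aa:
        raise ValueError(
            f"wild-type mismatch at {m.chain_id}:{m.seq_number}: "
            f"found {res.aa_type}, expected {m.wt_aa}")

    out = s.copy()
    target = out.get_residue(m.chain_id, m.seq_number)
    rng = np.random.default_rng(seed)
    _replace_side_chain(target, m.mut_aa, ())
    _optimize_side_chain(out, target, rng, params)

    ca = target.atom("CA")
    neighbours = []
    for other in out.residues():
        if other is target or other.atom("CA") is None:
            continue
        d = float(np.linalg.norm(ca.position - other.atom("CA").position))
        if d <= NEIGHBOUR_SHELL + 4.0 and N_CHI[other.aa_type] > 0:
            mind = min(np.linalg.norm(a.position - b.position)
                       for a in target.atoms for b in other.atoms)
            if mind <= NEIGHBOUR_SHELL:
                neighbours.append(other)
    for other in neighbours:
        _optimize_side_chain(out, other, rng, params)
    return annotate_structure(out)


def repair(s: Structure, seed: int = 0, params: ForceField | None = None,
           ctx: PHContext | None = None) -> Structure:
    """Re-optimize every side chain, accepting only energy improvements."""
    if params is None:
        params = get_params("v10")
    if ctx is None:
        ctx = PHContext()
    out = s.copy()
    annotate_structure(out)
    rng = np.random.default_rng(seed)
    energy = total_energy(out, ctx, params).total
    for res in out.residues():
        if N_CHI[res.aa_type] == 0:
            continue
        saved = [(a.name, a.element, a.position.copy()) for a in res.atoms]
        _optimize_side_chain(out, res, rng, params)
        annotate_structure(out)
        new_energy = total_energy(out, ctx, params).total
        if new_energy <= energy + 1e-9:
            energy = new_energy
        else:
            res.atoms = []
            for name, element, pos in saved:
                res.add_atom(Atom(name=name, element=element, position=pos))
            annotate_structure(out)
    return out


def ddg(wt: Structure, m: Mutation, ctx: PHContext | None = None,
        n_runs: int = 1, aggregate: str = "mean", seed: int = 0,
        params: ForceField | None = None) -> float:
    """ddG of a point mutation, kcal/mol (positive = destabilizing).

    Each run rebuilds both the mutant and a wild-type reference with the
    same seeded side-chain search and takes the total-energy difference;
    runs use seeds ``seed + i`` and are aggregated by mean or median.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    if params is None:
        params = get_params("v10")
    if ctx is None:
        ctx = PHContext()
    self_mut = Mutation(m.chain_id, m.seq_number, m.wt_aa, m.wt_aa)
    values = []
    for i in range(n_runs):
        run_seed = seed + i
        mutant = mutate(wt, m, seed=run_seed, params=params)
        reference = mutate(wt, self_mut, seed=run_seed, params=params)
        e_mut = total_energy(mutant, ctx, params).total
        e_wt = total_energy(reference, ctx, params).total
        values.append(e_mut - e_wt)
    values = np.asarray(values)
    return float(np.mean(values) if aggregate == "mean"
                 else np.median(values))


def ddg_runs(wt: Structure, m: Mutation, ctx: PHContext | None = None,
             n_runs: int = 5, seed: int = 0,
             params: ForceField | None = None) -> list[float]:
    """The individual per-run ddG values (same pairing as :func:`ddg`)."""
    return [ddg(wt, m, ctx, n_runs=1, aggregate="mean", seed=seed + i,
                params=params) for i in range(n_runs)]
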
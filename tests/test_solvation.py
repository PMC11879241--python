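"""Burial model, solvation energies and side-chain entropy."""

import numpy as np
import pytest
from scipy import stats

import ddgforge as dg
from ddgforge.residues import SIDECHAIN_ATOMS
from ddgforge.solvation import (
    atom_volume,
    min_max_buried,
    residue_side_chain_burial,
)
from ddgforge.structure import Atom, Residue, Structure, annotate_structure
from tests.conftest import rotation_matrix

# water->octanol side-chain transfer free energies (Fauchere-Pliska scale,
# kcal/mol, hydrophobic positive) used as the independent hydrophobicity
# reference for the rank-correlation smoke test
FP_HYDROPHOBICITY = {
    "TRP": 2.25, "ILE": 1.80, "PHE": 1.79, "LEU": 1.70, "CYS": 1.54,
    "MET": 1.23, "VAL": 1.22, "TYR": 0.96, "PRO": 0.72, "ALA": 0.31,
    "THR": 0.26, "HIS": 0.13, "GLY": 0.0, "SER": -0.04, "GLN": -0.22,
    "ASN": -0.60, "GLU": -0.64, "ASP": -0.77, "LYS": -0.99, "ARG": -1.01,
}


def lone_atom_structure():
    s = Structure()
    r = Residue("ALA", "A", 1)
    r.add_atom(Atom("CB", "C", [0.0, 0.0, 0.0]))
    s.add_residue(r)
    return annotate_structure(s), r.atom("CB")


def crowded_structure(n_shells=4):
    """An atom packed inside a dense cubic lattice of carbon neighbours."""
    s = Structure()
    r = Residue("ALA", "A", 1)
    r.add_atom(Atom("CB", "C", [0.0, 0.0, 0.0]))
    s.add_residue(r)
    k = 0
    for x in range(-n_shells, n_shells + 1):
        for y in range(-n_shells, n_shells + 1):
            for z in range(-n_shells, n_shells + 1):
                if x == y == z == 0:
                    continue
                k += 1
                other = Residue("ALA", "B", k)
                other.add_atom(Atom("CB", "C",
                                    2.0 * np.array([x, y, z], float)))
                s.add_residue(other)
    return annotate_structure(s), r.atom("CB")


class TestBuriedFraction:
    def test_isolated_atom_is_exposed(self):
        s, a = lone_atom_structure()
        assert dg.buried_fraction(a, s, dg.get_params("v10")) == 0.0

    def test_fully_packed_atom_clamps_to_one(self):
        s, a = crowded_structure()
        assert dg.buried_fraction(a, s, dg.get_params("v10")) == 1.0

    def test_v10_never_exceeds_v9(self, bundle):
        p9, p10 = dg.get_params("v9"), dg.get_params("v10")
        checked = 0
        for res in list(bundle.chains["A"])[3:7]:
            for a in res.atoms:
                f9 = dg.buried_fraction(a, bundle, p9)
                f10 = dg.buried_fraction(a, bundle, p10)
                assert f10 <= f9 + 1e-12
                if 0 < f9 < 1:
                    checked += 1
        assert checked > 5

    def test_v9_lower_than_v8_only_with_ring_neighbours(self, bundle):
        p8, p9 = dg.get_params("v8"), dg.get_params("v9")
        strict = 0
        for res in list(bundle.chains["A"])[3:7]:
            for a in res.atoms:
                f8 = dg.buried_fraction(a, bundle, p8)
                f9 = dg.buried_fraction(a, bundle, p9)
                assert f9 <= f8 + 1e-12
                if 0 < f8 < 1 and f9 < f8 - 1e-9:
                    strict += 1
        assert strict > 0, "ring neighbours should strictly lower v9 burial"

    def test_no_ring_neighbours_identical_v8_v9(self):
        s, a = crowded_structure(n_shells=2)
        from ddgforge.solvation import buried_volume
        assert buried_volume(a, s, dg.get_params("v8")) == \
            buried_volume(a, s, dg.get_params("v9"))

    def test_rigid_transform_invariance(self, helix_ser):
        p = dg.get_params("v10")
        a0 = list(helix_ser.chains["A"])[5].atom("CA")
        f0 = dg.buried_fraction(a0, helix_ser, p)
        moved = helix_ser.copy()
        rot = rotation_matrix([0.3, 1.0, -0.2], 1.1)
        shift = np.array([5.0, -3.0, 11.0])
        for at in moved.atoms():
            at.position = rot @ at.position + shift
        annotate_structure(moved)
        a1 = list(moved.chains["A"])[5].atom("CA")
        assert dg.buried_fraction(a1, moved, p) == pytest.approx(f0, abs=1e-9)

    def test_ring_volume_ratio_is_0_9(self):
        s = dg.make_ring_pair("PHE", "TYR", 4.5, 0.0)
        phe = [r for r in s.residues() if r.aa_type == "PHE"][0]
        cg = phe.atom("CG")
        v9 = atom_volume(cg, dg.get_params("v9"))
        v8 = atom_volume(cg, dg.get_params("v8"))
        assert v9 / v8 == pytest.approx(0.9)

    def test_v10_minimum_increment_is_10(self):
        s, a = lone_atom_structure()
        lo9, _ = min_max_buried(a, dg.get_params("v9"))
        lo10, _ = min_max_buried(a, dg.get_params("v10"))
        assert lo10 - lo9 == pytest.approx(10.0)

    def test_pro_ring_minimums(self):
        s = Structure()
        r = Residue("PRO", "A", 1)
        for name in ("CB", "CG", "CD"):
            r.add_atom(Atom(name, "C", np.random.default_rng(0).normal(size=3)))
        s.add_residue(r)
        p9, p10 = dg.get_params("v9"), dg.get_params("v10")
        assert min_max_buried(r.atom("CB"), p9)[0] == 157.0
        assert min_max_buried(r.atom("CG"), p9)[0] == 147.0
        assert min_max_buried(r.atom("CD"), p9)[0] == 170.0
        # v10: raised to the aromatic CB value (+ the global increment)
        assert min_max_buried(r.atom("CB"), p10)[0] == 197.0 + 10.0
        assert min_max_buried(r.atom("CD"), p10)[0] == 207.0 + 10.0


class TestSolvationEnergy:
    def _trp_atom(self, name, element):
        r = Residue("TRP", "A", 1)
        r.add_atom(Atom(name, element, [0.0, 0.0, 0.0]))
        return r.atom(name)

    def test_zero_burial_zero_energy(self):
        a = self._trp_atom("CZ2", "C")
        assert dg.solvation_energy(a, 0.0, dg.get_params("v10")) == 0.0

    def test_linearity_in_fraction(self):
        a = self._trp_atom("CZ2", "C")
        p = dg.get_params("v6")
        assert dg.solvation_energy(a, 0.5, p) == \
            pytest.approx(0.5 * dg.solvation_energy(a, 1.0, p))

    def test_trp_apolar_shift_v7_minus_v6(self):
        a = self._trp_atom("CZ2", "C")
        diff = dg.solvation_energy(a, 1.0, dg.get_params("v7")) \
            - dg.solvation_energy(a, 1.0, dg.get_params("v6"))
        assert diff == pytest.approx(-0.2)

    def test_trp_ring_nh_unchanged(self):
        a = self._trp_atom("NE1", "N")
        diff = dg.solvation_energy(a, 1.0, dg.get_params("v7")) \
            - dg.solvation_energy(a, 1.0, dg.get_params("v6"))
        assert diff == 0.0

    def test_hydrophobicity_rank_correlation(self):
        """Full-burial side-chain desolvation sums should track an
        independent water->octanol transfer scale."""
        p = dg.get_params("v10")
        gains = {}
        for aa, atoms in SIDECHAIN_ATOMS.items():
            r = Residue(aa, "A", 1)
            total = 0.0
            for name in atoms:
                el = name[0] if name[0] in "CNOS" else "C"
                r.add_atom(Atom(name, el, np.zeros(3)))
                total += dg.solvation_energy(r.atom(name), 1.0, p)
            gains[aa] = -total  # hydrophobic burial is favourable (negative)
        aas = sorted(gains)
        rho = stats.spearmanr([gains[a] for a in aas],
                              [FP_HYDROPHOBICITY[a] for a in aas]).statistic
        assert rho > 0.6


class TestEntropy:
    def test_met_v5_lookup(self):
        assert dg.get_params("v5").entropy_table["MET"] == 0.0073667

    def test_met_cost_raised_in_v5(self):
        r = Residue("MET", "A", 1)
        c1 = dg.side_chain_entropy(r, 0.8, 298.0,
                                   dg.get_params("v1").entropy_table)
        c5 = dg.side_chain_entropy(r, 0.8, 298.0,
                                   dg.get_params("v5").entropy_table)
        assert c5 > c1 > 0.0

    def test_met_exceeds_gln_in_v5(self):
        t = dg.get_params("v5").entropy_table
        assert t["MET"] > t["GLN"]

    def test_zero_burial_costs_nothing(self):
        r = Residue("LYS", "A", 1)
        assert dg.side_chain_entropy(r, 0.0, 298.0,
                                     dg.get_params("v10").entropy_table) == 0.0

    def test_burial_out_of_range_rejected(self):
        r = Residue("LYS", "A", 1)
        with pytest.raises(ValueError):
            dg.side_chain_entropy(r, 1.5, 298.0,
                                  dg.get_params("v10").entropy_table)


def test_unknown_element_rejected():
    s = Structure()
    r = Residue("ALA", "A", 1)
    r.add_atom(Atom("XX", "X", [0.0, 0.0, 0.0]))
    s.add_residue(r)
    with pytest.raises(KeyError, match="X"):
        atom_volume(r.atom("XX"), dg.get_params("v10"))
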
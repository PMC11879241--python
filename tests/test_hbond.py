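"""H-bond window semantics, special cases and geometric invariants."""

import math

import numpy as np
import pytest

import ddgforge as dg
from ddgforge.hbond import dihedral_weight, window_weight
from ddgforge.structure import (
    Atom,
    DummyKind,
    DummySite,
    Residue,
    Structure,
)


def _basis_about(axis):
    axis = axis / np.linalg.norm(axis)
    probe = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(probe, axis)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    x = probe - np.dot(probe, axis) * axis
    x /= np.linalg.norm(x)
    y = np.cross(axis, x)
    return x, y


def build_pair(fpd: float, pfa: float, dihed: float) -> Structure:
    """Synthetic Ser-OG -> Asn-OD1 pair with exact freeProtDon/protFreeAcc
    angles and a dihedral solved numerically to the requested value."""
    d_pos = np.array([0.0, 0.0, 0.0])
    h_pos = np.array([1.0, 0.0, 0.0])
    a1 = math.radians(180.0 - fpd)
    orb_pos = h_pos + 0.8 * np.array([math.cos(a1), math.sin(a1), 0.0])

    z = (h_pos - orb_pos) / np.linalg.norm(h_pos - orb_pos)
    x, y = _basis_about(z)
    t = math.radians(pfa)
    best = None
    for phi_deg in np.arange(0.0, 360.0, 0.05):
        phi = math.radians(phi_deg)
        e = (math.cos(t) * z
             + math.sin(t) * (math.cos(phi) * x + math.sin(phi) * y))
        a_pos = orb_pos + 0.9 * e
        got = dg.dihedral_angle(d_pos, h_pos, orb_pos, a_pos)
        err = abs(got - dihed)
        err = min(err, 360 - err)
        if best is None or err < best[0]:
            best = (err, a_pos)
    a_pos = best[1]
    assert 2.0 <= np.linalg.norm(a_pos - d_pos) <= 3.5

    s = Structure()
    ser = Residue("SER", "A", 1)
    ser.add_atom(Atom("OG", "O", d_pos))
    asn = Residue("ASN", "A", 5)
    asn.add_atom(Atom("OD1", "O", a_pos))
    s.add_residue(ser)
    s.add_residue(asn)
    s.dummy_sites = [
        DummySite(DummyKind.PROTON, h_pos, owner=ser,
                  parent_atom=ser.atom("OG")),
        DummySite(DummyKind.FREE_ORBITAL, orb_pos, owner=asn,
                  parent_atom=asn.atom("OD1")),
    ]
    s.annotated = True
    return s


SC = {"minFreeProtDon": 90, "optMinFreeProtDon": 115,
      "optMaxFreeProtDon": 170, "maxFreeProtDon": 180,
      "minProtFreeAcc": 70, "optMinProtFreeAcc": 90,
      "optMaxProtFreeAcc": 160, "maxProtFreeAcc": 180,
      "optDihed": 170}


class TestWindowSemantics:
    def test_all_angles_optimal_gives_full_base_energy(self):
        s = build_pair(fpd=150.0, pfa=120.0, dihed=170.0)
        table = dg.get_params("v8").hbond_geometry
        bonds = dg.detect_and_score_hbonds(s, table, base_energy=-1.32)
        assert len(bonds) == 1
        b = bonds[0]
        assert b.klass == "SC-SC"
        assert b.geometry_weight == pytest.approx(1.0, abs=1e-3)
        assert b.energy == pytest.approx(-1.32, abs=2e-3)

    def test_angle_below_hard_minimum_rejected(self):
        s = build_pair(fpd=85.0, pfa=120.0, dihed=170.0)  # SC min is 90
        table = dg.get_params("v8").hbond_geometry
        assert dg.detect_and_score_hbonds(s, table) == []

    def test_midway_ramp_gives_half_weight(self):
        midway = (SC["minFreeProtDon"] + SC["optMinFreeProtDon"]) / 2
        s = build_pair(fpd=midway, pfa=120.0, dihed=170.0)
        table = dg.get_params("v8").hbond_geometry
        bonds = dg.detect_and_score_hbonds(s, table)
        assert len(bonds) == 1
        b = bonds[0]
        expected = 0.5 * dihedral_weight(b.dihed, SC["optDihed"])
        assert b.geometry_weight == pytest.approx(expected, abs=1e-6)

    def test_weight_continuous_across_opt_min_boundary(self):
        table = dg.get_params("v8").hbond_geometry
        lo = SC["optMinFreeProtDon"] - 0.05
        hi = SC["optMinFreeProtDon"] + 0.05
        w_lo = window_weight(lo, SC["minFreeProtDon"],
                             SC["optMinFreeProtDon"],
                             SC["optMaxFreeProtDon"], SC["maxFreeProtDon"])
        w_hi = window_weight(hi, SC["minFreeProtDon"],
                             SC["optMinFreeProtDon"],
                             SC["optMaxFreeProtDon"], SC["maxFreeProtDon"])
        assert abs(w_hi - w_lo) < 0.01
        del table

    def test_reported_bonds_respect_hard_windows(self, bundle):
        table = dg.get_params("v8").hbond_geometry
        bonds = dg.detect_and_score_hbonds(s=bundle, table=table)
        assert bonds, "bundle fixture should contain H-bonds"
        for b in bonds:
            tbl = table.for_class(b.klass)
            assert tbl["minFreeProtDon"] <= b.freeProtDon \
                <= tbl["maxFreeProtDon"]
            assert tbl["minProtFreeAcc"] <= b.protFreeAcc \
                <= tbl["maxProtFreeAcc"]
            assert 0.0 < b.geometry_weight <= 1.0
            assert b.energy <= 0.0


class TestSaltBridge:
    def test_front_pattern_detected_with_factor(self, salt_bridge):
        p2 = dg.get_params("v2")
        bonds = dg.detect_and_score_hbonds(
            salt_bridge, p2.hbond_geometry,
            base_energy=p2.hbond["neutral_energy"],
            charged_energy=p2.hbond["charged_energy"])
        arg, asp = list(salt_bridge.residues())
        mode, factor = dg.double_salt_bridge(arg, asp, bonds, p2)
        assert mode is dg.SaltBridgeMode.FRONT
        assert factor == 1.5
        donors = {b.donor.name for b in bonds}
        assert {"NH1", "NH2"} <= donors

    def test_v1_factor_is_one(self, salt_bridge):
        p1 = dg.get_params("v1")
        bonds = dg.detect_and_score_hbonds(
            salt_bridge, p1.hbond_geometry,
            base_energy=p1.hbond["neutral_energy"],
            charged_energy=p1.hbond["charged_energy"])
        arg, asp = list(salt_bridge.residues())
        mode, factor = dg.double_salt_bridge(arg, asp, bonds, p1)
        assert mode is dg.SaltBridgeMode.FRONT
        assert factor == 1.0

    def test_v2_v1_energy_ratio_is_exactly_1_5(self, salt_bridge, ctx):
        energies = {}
        for v in ("v1", "v2"):
            p = dg.get_params(v)
            energies[v] = dg.total_energy(salt_bridge, ctx, p).terms["hbond"]
        assert energies["v2"] / energies["v1"] == pytest.approx(1.5)

    def test_distant_pair_gives_none(self):
        s = dg.make_salt_bridge(n_o_distance=6.0)
        p = dg.get_params("v10")
        bonds = dg.detect_and_score_hbonds(s, p.hbond_geometry)
        arg, asp = list(s.residues())
        mode, factor = dg.double_salt_bridge(arg, asp, bonds, p)
        assert mode is dg.SaltBridgeMode.NONE
        assert factor == 1.0

    def test_non_arg_input_rejected(self, salt_bridge):
        arg, asp = list(salt_bridge.residues())
        with pytest.raises(ValueError):
            dg.double_salt_bridge(asp, asp, [])


class TestNcap:
    @pytest.mark.parametrize("aa,version,expected", [
        ("THR", "v4", -2.64),
        ("SER", "v1", -1.32),
        ("SER", "v4", -1.98),
        ("ASN", "v4", -1.98),
        ("ASP", "v4", -1.32),
        ("ALA", "v4", 0.0),
    ])
    def test_ncap_bonus_values(self, aa, version, expected):
        s = dg.make_helix_peptide(10, ncap_aa=aa)
        bonus = dg.ncap_bonus(s.helices[0], s, dg.get_params(version))
        assert bonus == pytest.approx(expected)

    def test_base_energy_recovered_from_multiplier(self):
        s = dg.make_helix_peptide(10, ncap_aa="SER")
        p4 = dg.get_params("v4")
        bonus = dg.ncap_bonus(s.helices[0], s, p4)
        assert abs(bonus) / p4.ncap_multipliers["SER"] == pytest.approx(1.32)


def test_dihedral_weight_peak_and_decay():
    assert dihedral_weight(170.0, 170.0) == 1.0
    assert dihedral_weight(-170.0, 170.0) == 1.0
    assert dihedral_weight(0.0, 170.0) == 0.0
    assert 0.0 < dihedral_weight(100.0, 170.0) < 1.0
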
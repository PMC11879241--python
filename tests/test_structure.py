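"""Structure model: PDB I/O, dummy-site placement and geometry kernels."""

import math
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ddgforge as dg
from ddgforge.structure import (
    DummyKind,
    ParseError,
    detect_helices_geometric,
    fit_plane,
)
from tests.conftest import rotation_matrix

MINI_PDB = textwrap.dedent("""\
    REMARK   2 RESOLUTION.    1.50 ANGSTROMS.
    EXPDTA    X-RAY DIFFRACTION
    ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
    ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
    ATOM      3  C   ALA A   1      10.674   5.946  -3.984  1.00  0.00           C
    ATOM      4  O   ALA A   1       9.902   5.000  -3.984  1.00  0.00           O
    ATOM      5  CB  ALA A   1      12.600   7.200  -4.900  1.00  0.00           C
    ATOM      6  N   GLY A   2      10.600   6.900  -3.000  1.00  0.00           N
    ATOM      7  CA  GLY A   2       9.700   6.900  -1.900  1.00  0.00           C
    ATOM      8  C   GLY A   2       8.600   7.900  -2.100  1.00  0.00           C
    ATOM      9  O   GLY A   2       8.700   9.000  -1.600  1.00  0.00           O
    ATOM     10  N   SER A   3       7.600   7.500  -2.900  1.00  0.00           N
    ATOM     11  CA  SER A   3       6.500   8.400  -3.200  1.00  0.00           C
    ATOM     12  C   SER A   3       5.300   7.600  -3.700  1.00  0.00           C
    ATOM     13  O   SER A   3       5.400   6.400  -3.900  1.00  0.00           O
    ATOM     14  CB  SER A   3       7.000   9.400  -4.300  1.00  0.00           C
    ATOM     15  OG  SER A   3       7.900  10.300  -3.700  1.00  0.00           O
    END
""")


class TestReadStructure:
    def test_counts_resolution_method(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINI_PDB)
        s = dg.read_structure(str(p))
        assert s.n_atoms() == 15
        assert sum(1 for _ in s.residues()) == 3
        assert s.resolution == pytest.approx(1.50)
        assert s.experimental_method is dg.ExperimentalMethod.XRAY

    def test_nmr_method_without_resolution(self, tmp_path):
        text = MINI_PDB.replace("EXPDTA    X-RAY DIFFRACTION",
                                "EXPDTA    SOLUTION NMR")
        text = "\n".join(ln for ln in text.splitlines()
                         if not ln.startswith("REMARK")) + "\n"
        p = tmp_path / "nmr.pdb"
        p.write_text(text)
        s = dg.read_structure(str(p))
        assert s.experimental_method is dg.ExperimentalMethod.NMR
        assert s.resolution is None

    def test_malformed_atom_line_names_line_number(self, tmp_path):
        bad = MINI_PDB.replace("11.104", "xx.xxx")
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(ParseError, match=":3:"):
            dg.read_structure(str(p))

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ParseError):
            dg.read_structure(str(p))

    def test_round_trip_preserves_atoms(self, helix_ser, tmp_path):
        p = tmp_path / "rt.pdb"
        dg.write_structure(helix_ser, str(p))
        back = dg.read_structure(str(p))
        assert back.n_atoms() == helix_ser.n_atoms()
        orig = np.array([a.position for a in helix_ser.atoms()])
        rt = np.array([a.position for a in back.atoms()])
        assert np.abs(orig - rt).max() <= 1e-3
        assert [a.name for a in back.atoms()] == \
            [a.name for a in helix_ser.atoms()]
        assert [(h.start_seq, h.end_seq) for h in back.helices] == [(2, 10)]


class TestAnnotation:
    def test_helix_gets_one_dipole_pair(self, helix_ala):
        ncaps = [d for d in helix_ala.dummy_sites
                 if d.kind is DummyKind.NCAP_DIPOLE]
        ccaps = [d for d in helix_ala.dummy_sites
                 if d.kind is DummyKind.CCAP_DIPOLE]
        assert len(ncaps) == 1 and len(ccaps) == 1
        assert ncaps[0].charge == +0.5
        assert ccaps[0].charge == -0.5

    def test_ncap_dipole_is_centroid_of_first_four_nitrogens(self, helix_ala):
        helix = helix_ala.helices[0]
        members = [r for r in helix_ala.chains["A"]
                   if helix.start_seq <= r.seq_number <= helix.end_seq]
        expected = np.mean([r.atom("N").position for r in members[:4]], axis=0)
        ncap = [d for d in helix_ala.dummy_sites
                if d.kind is DummyKind.NCAP_DIPOLE][0]
        assert np.allclose(ncap.position, expected)

    def test_dipole_invariant_under_atom_order(self, helix_ala):
        shuffled = helix_ala.copy()
        for res in shuffled.residues():
            res.atoms = res.atoms[::-1]
        dg.annotate_structure(shuffled)
        for kind in (DummyKind.NCAP_DIPOLE, DummyKind.CCAP_DIPOLE):
            a = [d.position for d in helix_ala.dummy_sites if d.kind is kind]
            b = [d.position for d in shuffled.dummy_sites if d.kind is kind]
            assert np.allclose(a, b)

    def test_his_ring_centroid_is_mean_of_ring_atoms(self):
        s = dg.make_ring_pair("HIS", "TRP", 4.5, 0.0)
        his = [r for r in s.residues() if r.aa_type == "HIS"][0]
        ring = ["CG", "ND1", "CD2", "CE1", "NE2"]
        expected = np.mean([his.atom(n).position for n in ring], axis=0)
        cents = [d for d in s.dummy_sites
                 if d.kind is DummyKind.RING_CENTROID and d.owner is his]
        assert len(cents) == 1
        assert np.allclose(cents[0].position, expected)

    def test_geometric_helix_detection(self, helix_ala):
        bare = helix_ala.copy()
        bare.helices = []
        found = detect_helices_geometric(bare)
        assert len(found) == 1
        assert found[0].end_seq - found[0].start_seq >= 7


class TestGeometryKernels:
    def test_plane_angle_trivials(self):
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        assert dg.plane_angle(sq, sq + [0, 0, 2.0]) == pytest.approx(0.0)
        vert = np.array([[0, 0, 0], [0, 1, 0], [0, 1, 1], [0, 0, 1]], float)
        assert dg.plane_angle(sq, vert) == pytest.approx(90.0)

    def test_plane_angle_rotation_oracle(self):
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        rot = rotation_matrix([1.0, 0.0, 0.0], math.radians(30))
        assert dg.plane_angle(sq, sq @ rot.T) == pytest.approx(30.0, abs=1e-6)

    def test_collinear_points_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(ValueError):
            fit_plane(line)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_plane_angle_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.normal(size=(5, 3))
        g2 = rng.normal(size=(4, 3))
        rot = rotation_matrix(rng.normal(size=3), rng.uniform(0, math.pi))
        shift = rng.normal(size=3) * 10
        a = dg.plane_angle(g1, g2)
        b = dg.plane_angle(g1 @ rot.T + shift, g2 @ rot.T + shift)
        assert a == pytest.approx(b, abs=1e-9)
        assert dg.plane_angle(g2, g1) == pytest.approx(a, abs=1e-9)
        assert 0.0 <= a <= 90.0

    def test_dihedral_trivials(self):
        assert abs(dg.dihedral_angle([0, 0, 0], [1, 0, 0], [1, 1, 0],
                                     [1, 1, 1])) == pytest.approx(90.0)
        assert dg.dihedral_angle([0, 1, 0], [0, 0, 0], [1, 0, 0],
                                 [1, -1, 0]) == pytest.approx(180.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_dihedral_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 3
        a, b, c, d = pts

        # independent construction: project onto the plane normal to b-c
        axis = (c - b) / np.linalg.norm(c - b)
        v1 = (a - b) - np.dot(a - b, axis) * axis
        v2 = (d - c) - np.dot(d - c, axis) * axis
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
        if np.dot(np.cross(v1, v2), axis) > 0:
            ang = -ang
        got = dg.dihedral_angle(a, b, c, d)
        assert math.isclose(math.sin(math.radians(got)),
                            math.sin(math.radians(ang)), abs_tol=1e-9)
        assert math.isclose(math.cos(math.radians(got)),
                            math.cos(math.radians(ang)), abs_tol=1e-9)

    def test_dihedral_coincident_points_error(self):
        with pytest.raises(ValueError):
            dg.dihedral_angle([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
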
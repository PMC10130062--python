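"""M(Cys)4 first/second coordination sphere and crystal contacts."""

import numpy as np
import pytest

from minimet import fixtures
from minimet.geometry_core import Transform
from minimet.metal_site import (
    RUBREDOXIN_ZN_REFERENCE,
    TETRAHEDRAL_ANGLE,
    ReferenceStats,
    analyze_site,
    compare_to_reference,
    crystal_contact_report,
    detect_nh_s_hbonds,
    find_metal_site,
    first_shell_geometry,
)
from minimet.structure_io import Atom, Residue, Structure, StructureError


class TestFindSite:
    def test_ideal_site_has_four_thiolates(self, ideal_site):
        site = find_metal_site(ideal_site, "Zn")
        assert site.coordination_number == 4
        assert [r.seq_id for r, _ in site.ligands] == [2, 5, 17, 20]
        assert all(a.name == "SG" for _, a in site.ligands)

    def test_three_coordinate_site_is_flagged(self, ideal_site):
        st = ideal_site.copy()
        st.chains["A"] = [r for r in st.chains["A"] if r.seq_id != 17]
        report = first_shell_geometry(find_metal_site(st, "Zn"))
        assert any("coordination number 3" in f for f in report.flags)

    def test_no_metal_is_an_error(self):
        st = fixtures.backbone_from_dihedrals([(-60.0, -40.0, 180.0)] * 4)
        with pytest.raises(StructureError):
            find_metal_site(st, "Zn")

    def test_two_metals_need_a_selector(self, ideal_site):
        st = ideal_site.copy()
        extra = Residue(name="ZN", seq_id=199, chain_id="A")
        extra.add_atom(Atom("ZN", "Zn", [30.0, 0.0, 0.0], is_hetero=True))
        st.add_residue(extra)
        with pytest.raises(StructureError, match="disambiguate"):
            find_metal_site(st, "Zn")
        site = find_metal_site(st, "Zn", metal_seq=("A", 99))
        assert site.coordination_number == 4


class TestFirstShell:
    def test_ideal_geometry(self, ideal_site):
        report = first_shell_geometry(find_metal_site(ideal_site, "Zn"))
        np.testing.assert_allclose(report.distances, 2.34, atol=1e-9)
        np.testing.assert_allclose(report.angles, TETRAHEDRAL_ANGLE, atol=1e-6)
        assert report.tetrahedricity == pytest.approx(0.0, abs=1e-6)
        assert report.torsions == pytest.approx([180.0, 159.0], abs=1e-6)
        assert report.chi1_classes == {
            "CYS2": "t", "CYS5": "g+", "CYS17": "t", "CYS20": "g+"
        }

    def test_custom_bond_length(self):
        st = fixtures.make_ideal_site(d=2.30)
        report = first_shell_geometry(find_metal_site(st, "Zn"))
        assert report.mean_distance == pytest.approx(2.30, abs=1e-9)

    def test_constructed_distortion_matches_analytics(self):
        """Compressing the tetrahedron along z changes the six S-M-S
        angles exactly as the constructed vertex geometry dictates."""
        st = fixtures.make_ideal_site()
        factor = 0.8
        for res in st.chains["A"]:
            if res.name == "CYS":
                res.atom("SG").coords = res.atom("SG").coords * np.array([1.0, 1.0, factor])
        report = first_shell_geometry(find_metal_site(st, "Zn"))
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, -1, 1], [-1, 1, -1]]) / np.sqrt(3)
        verts = verts * np.array([1.0, 1.0, factor])
        expected = []
        for i in range(4):
            for j in range(i + 1, 4):
                c = verts[i] @ verts[j] / (
                    np.linalg.norm(verts[i]) * np.linalg.norm(verts[j])
                )
                expected.append(np.degrees(np.arccos(c)))
        np.testing.assert_allclose(report.angles, expected, atol=1e-6)
        assert report.tetrahedricity > 1.0

    def test_rigid_motion_invariance(self, ideal_site, rng):
        moved = ideal_site.copy()
        tf = Transform.about_axis(rng.normal(size=3), rng.normal(size=3), 51.0)
        for atom in moved.atoms():
            atom.coords = tf.apply(atom.coords) + np.array([7.0, -3.0, 2.0])
        a = first_shell_geometry(find_metal_site(ideal_site, "Zn"))
        b = first_shell_geometry(find_metal_site(moved, "Zn"))
        np.testing.assert_allclose(b.distances, a.distances, atol=1e-9)
        np.testing.assert_allclose(b.angles, a.angles, atol=1e-9)
        np.testing.assert_allclose(b.torsions, a.torsions, atol=1e-6)


def _nh_s_fixture(aim_at_sulfur=True):
    """One Cys SG plus a donor residue with an explicit amide H."""
    st = Structure(name="nh_s")
    cys = Residue(name="CYS", seq_id=5, chain_id="A")
    cys.add_atom(Atom("SG", "S", [0.0, 0.0, 0.0]))
    st.add_residue(cys)
    don = Residue(name="ALA", seq_id=7, chain_id="A")
    n = np.array([3.4, 0.0, 0.0])
    h_dir = np.array([-1.0, 0.0, 0.0]) if aim_at_sulfur else np.array([0.5, np.sqrt(3) / 2, 0.0])
    don.add_atom(Atom("N", "N", n))
    don.add_atom(Atom("H", "H", n + h_dir))
    don.add_atom(Atom("CA", "C", n + [1.0, 1.0, 0.0]))
    st.add_residue(don)
    return st, cys


class TestSecondSphere:
    def test_aimed_nh_detected(self):
        st, cys = _nh_s_fixture(aim_at_sulfur=True)
        backbone, _ = detect_nh_s_hbonds(st, [(cys, cys.atom("SG"))])
        assert len(backbone) == 1
        assert backbone[0].donor == ("A", 7, "N")
        assert backbone[0].distance_da == pytest.approx(3.4)

    def test_averted_nh_not_detected(self):
        st, cys = _nh_s_fixture(aim_at_sulfur=False)
        backbone, _ = detect_nh_s_hbonds(st, [(cys, cys.atom("SG"))])
        assert backbone == []

    def test_detection_is_monotone_in_criteria(self):
        st, cys = _nh_s_fixture(aim_at_sulfur=True)
        strict = {"d_NS_max": 3.45, "d_HS_max": 2.5, "angle_NHS_min": 150.0}
        loose = {"d_NS_max": 3.8, "d_HS_max": 3.1, "angle_NHS_min": 110.0}
        got_strict, _ = detect_nh_s_hbonds(st, [(cys, cys.atom("SG"))], strict)
        got_loose, _ = detect_nh_s_hbonds(st, [(cys, cys.atom("SG"))], loose)
        strict_keys = {(b.donor, b.acceptor) for b in got_strict}
        loose_keys = {(b.donor, b.acceptor) for b in got_loose}
        assert strict_keys <= loose_keys

    def test_sidechain_amide_donor(self):
        st = Structure(name="asn")
        cys = Residue(name="CYS", seq_id=5, chain_id="A")
        cys.add_atom(Atom("SG", "S", [0.0, 0.0, 0.0]))
        st.add_residue(cys)
        asn = Residue(name="ASN", seq_id=19, chain_id="A")
        asn.add_atom(Atom("ND2", "N", [3.3, 0.0, 0.0]))
        asn.add_atom(Atom("CG", "C", [4.6, 0.5, 0.0]))
        st.add_residue(asn)
        _, sidechain = detect_nh_s_hbonds(st, [(cys, cys.atom("SG"))])
        assert [b.donor for b in sidechain] == [("A", 19, "ND2")]


class TestCrystalContacts:
    def test_isolated_molecule_in_p1_has_no_contacts(self):
        st = fixtures.make_ideal_site()
        st.unit_cell = (100.0, 100.0, 100.0, 90.0, 90.0, 90.0)
        st.space_group = "P 1"
        st.sym_ops = [(np.eye(3), np.zeros(3))]
        assert crystal_contact_report(st) == []

    def test_missing_cell_is_an_error(self, ideal_site):
        with pytest.raises(StructureError):
            crystal_contact_report(ideal_site)

    def test_engineered_cell_reproduces_planted_contacts(self):
        st = fixtures.make_crystal_contact_fixture()
        contacts = crystal_contact_report(st, radius=4.0)
        oh = [
            c for c in contacts
            if c.atom[2:] == ("TYR", "OH") and c.mate_atom[2:] == ("TYR", "OH")
        ]
        assert oh and min(c.distance for c in oh) == pytest.approx(3.32, abs=1e-6)
        bridges = [c for c in contacts if c.kind == "salt-bridge"]
        assert any(
            {"ARG", "ASP"} == {c.atom[2], c.mate_atom[2]} for c in bridges
        )
        arg_sg = [
            c for c in contacts
            if {c.atom[2], c.mate_atom[2]} == {"ARG", "CYS"} and c.kind == "h-bond"
        ]
        assert arg_sg and min(c.distance for c in arg_sg) == pytest.approx(3.3, abs=1e-6)


class TestReferenceComparison:
    def test_zero_z_at_the_mean(self):
        report = first_shell_geometry(find_metal_site(fixtures.make_ideal_site(d=2.34), "Zn"))
        z = compare_to_reference(report)
        assert z["mean_distance"] == pytest.approx(0.0, abs=1e-9)

    def test_two_sigma_distance(self):
        report = first_shell_geometry(find_metal_site(fixtures.make_ideal_site(d=2.40), "Zn"))
        z = compare_to_reference(report)
        assert z["mean_distance"] == pytest.approx(2.0, abs=1e-9)

    def test_ideal_site_within_one_sigma_of_survey(self, ideal_site):
        report = first_shell_geometry(find_metal_site(ideal_site, "Zn"))
        z = compare_to_reference(report, RUBREDOXIN_ZN_REFERENCE)
        assert abs(z["mean_distance"]) <= 1.0
        assert abs(z["mean_angle"]) <= 1.0

    def test_zero_sd_rejected(self, ideal_site):
        report = first_shell_geometry(find_metal_site(ideal_site, "Zn"))
        with pytest.raises(ValueError):
            compare_to_reference(report, ReferenceStats(2.34, 0.0, 109.0, 4.0))


def test_analyze_site_collects_everything(ideal_site):
    report = analyze_site(ideal_site, "Zn")
    assert len(report.distances) == 4 and len(report.angles) == 6
    assert report.metal_element.upper() == "ZN"
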
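"""Geometry: H-bond detection vs oracle, chi angles, rotamers, SASA."""

import numpy as np
import pytest
import biotite.structure as struc

from qhelix.builder import build_ideal_helix, dihedral_deg, get_chi, set_chi
from qhelix.geometry import (
    HBondCriteria,
    atom_radii,
    classify_chi,
    classify_rotamer,
    default_acceptors,
    default_donors,
    detect_hbonds,
    fibonacci_sphere,
    sasa,
    trajectory_summary,
)
from qhelix.ensemble import Ensemble


def make_frame(atoms):
    """atoms: list of (res_id, res_name, atom_name, element, coord)."""
    return struc.array(
        [
            struc.Atom(c, chain_id="A", res_id=r, res_name=rn, atom_name=an,
                       element=el, hetero=False)
            for r, rn, an, el, c in atoms
        ]
    )


def brute_force_hbonds(frame, criteria, donors, acceptors):
    """Independent O(n^2) scan with its own distance/angle arithmetic."""
    found = []
    for heavy, h in donors:
        for acc in acceptors:
            if acc == heavy:
                continue
            v1 = frame.coord[heavy] - frame.coord[h]
            v2 = frame.coord[acc] - frame.coord[h]
            d = np.sqrt((v2 ** 2).sum())
            cosang = (v1 * v2).sum() / np.sqrt((v1**2).sum() * (v2**2).sum())
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if d < criteria.max_dist_H_acceptor and ang > criteria.min_angle_donor_H_acceptor:
                found.append((heavy, h, acc))
    return sorted(found)


class TestDetectHbonds:
    def linear_nho(self, dist, angle_deg):
        """N-H along x; O at the given H..O distance and N-H..O angle."""
        theta = np.radians(180.0 - angle_deg)
        o = np.array([1.01 + dist * np.cos(theta), dist * np.sin(theta), 0.0])
        return make_frame(
            [
                (1, "ALA", "N", "N", np.zeros(3)),
                (1, "ALA", "H", "H", np.array([1.01, 0.0, 0.0])),
                (2, "ALA", "O", "O", o),
            ]
        )

    def test_just_inside_both_cutoffs(self):
        frame = self.linear_nho(2.39, 121.0)
        bonds = detect_hbonds(frame, donors=[(0, 1)], acceptors=[2])
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.39, abs=1e-4)
        assert bonds[0].angle == pytest.approx(121.0, abs=1e-3)

    def test_distance_cutoff_excludes(self):
        frame = self.linear_nho(2.41, 179.0)
        assert detect_hbonds(frame, donors=[(0, 1)], acceptors=[2]) == []

    def test_angle_cutoff_excludes(self):
        frame = self.linear_nho(2.0, 119.0)
        assert detect_hbonds(frame, donors=[(0, 1)], acceptors=[2]) == []

    def test_mt_gln_sidechain_bond_and_oracle(self, helix_llllq):
        frame = helix_llllq.frame(0)
        criteria = HBondCriteria()
        donors = default_donors(frame)
        acceptors = default_acceptors(frame)
        bonds = detect_hbonds(frame, criteria, donors, acceptors)
        # Gln8 side chain donates to Leu4 main-chain O
        ne2 = helix_llllq.atom_index(8, "NE2")
        o4 = helix_llllq.atom_index(4, "O")
        assert any(b.donor_index == ne2 and b.acceptor_index == o4 for b in bonds)
        # full agreement with the brute-force oracle
        got = sorted((b.donor_index, b.h_index, b.acceptor_index) for b in bonds)
        assert got == brute_force_hbonds(frame, criteria, donors, acceptors)

    def test_bifurcated_flag(self, helix_llllq):
        frame = helix_llllq.frame(0)
        bonds = detect_hbonds(frame)
        o4 = helix_llllq.atom_index(4, "O")
        to_o4 = [b for b in bonds if b.acceptor_index == o4
                 and frame.res_id[b.donor_index] == 8]
        kinds = {frame.atom_name[b.h_index] for b in to_o4}
        assert "H" in kinds and kinds & {"HE21", "HE22"}
        assert all(b.bifurcated for b in to_o4)

    def test_non_hydrogen_donor_rejected(self):
        frame = self.linear_nho(2.0, 170.0)
        with pytest.raises(ValueError, match="not a hydrogen"):
            detect_hbonds(frame, donors=[(0, 2)], acceptors=[2])


class TestChiAngles:
    def test_roundtrip_built_chi(self):
        ens = build_ideal_helix("LLLQ", rotamers={4: {1: -60.0, 2: 180.0}})
        assert get_chi(ens.frame(0), 4, 1) == pytest.approx(-60.0, abs=1.0)
        assert get_chi(ens.frame(0), 4, 2) == pytest.approx(180.0, abs=1.0)

    def test_planar_zigzag_is_trans(self):
        p = [np.array([0.0, 0, 0]), np.array([1.5, 0, 0]),
             np.array([2.25, 1.3, 0]), np.array([3.75, 1.3, 0])]
        assert dihedral_deg(*p) == pytest.approx(180.0, abs=1e-6)

    def test_against_biotite_dihedral(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pts = rng.normal(size=(4, 3))
            ref = np.degrees(struc.dihedral(*[struc.Atom(p) for p in pts]))
            assert dihedral_deg(*pts) == pytest.approx(float(ref), abs=1e-4)

    def test_missing_sidechain_rejected(self):
        ens = build_ideal_helix("AG")
        with pytest.raises(ValueError, match="chi"):
            get_chi(ens.frame(0), 1, 1)

    def test_set_chi_is_exact(self):
        ens = build_ideal_helix("QQQQ")
        frame = ens.frame(0).copy()
        for target in (-170.0, -60.0, 45.0, 180.0):
            set_chi(frame, 2, 2, target)
            assert get_chi(frame, 2, 2) == pytest.approx(target, abs=1e-4)


class TestClassifyRotamer:
    @pytest.mark.parametrize(
        "chi1, chi2, label",
        [(-60, 180, "mt"), (175, 65, "tp"), (-119.9, 180, "mt"),
         (60, -60, "pm"), (150, -170, "tt")],
    )
    def test_examples(self, chi1, chi2, label):
        assert classify_rotamer(chi1, chi2).label == label

    def test_boundary_tie_rule(self):
        # half-open windows [center-60, center+60): -120 opens the m window
        assert classify_chi(-120.0) == "m"
        assert classify_chi(-119.999) == "m"
        assert classify_chi(-0.001) == "m"
        assert classify_chi(0.0) == "p"
        assert classify_chi(120.0) == "t"

    def test_wrap_invariance(self):
        rng = np.random.default_rng(1)
        for chi in rng.uniform(-180, 180, 50):
            assert classify_chi(chi) == classify_chi(chi + 360) == classify_chi(chi - 360)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        frame = make_frame([(1, "ALA", "CB", "C", np.zeros(3))])
        area = sasa(frame, [0])[0]
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=0.01)

    def test_fully_caged_atom_is_zero(self):
        cage = [(1, "ALA", "CB", "C", np.zeros(3))]
        # octahedral + cubic shell of overlapping spheres
        for k, v in enumerate(
            [v for v in
             [(2.2, 0, 0), (-2.2, 0, 0), (0, 2.2, 0), (0, -2.2, 0),
              (0, 0, 2.2), (0, 0, -2.2),
              (1.6, 1.6, 1.6), (1.6, 1.6, -1.6), (1.6, -1.6, 1.6),
              (-1.6, 1.6, 1.6), (1.6, -1.6, -1.6), (-1.6, 1.6, -1.6),
              (-1.6, -1.6, 1.6), (-1.6, -1.6, -1.6)]]
        ):
            cage.append((2, "ALA", "CB", "C", np.array(v, dtype=float)))
        frame = make_frame(cage)
        assert sasa(frame, [0])[0] == 0.0

    def test_two_spheres_match_dense_grid_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            d = rng.uniform(1.0, 5.0)
            frame = make_frame(
                [(1, "ALA", "CB", "C", np.zeros(3)),
                 (1, "ALA", "O", "O", np.array([d, 0.0, 0.0]))]
            )
            fast = sasa(frame, [0], n_points=960)[0]
            dense = sasa(frame, [0], n_points=20000)[0]
            assert fast == pytest.approx(dense, rel=0.02, abs=0.5)

    def test_convergence_toward_dense_grid(self):
        frame = make_frame(
            [(1, "ALA", "CB", "C", np.zeros(3)),
             (1, "ALA", "O", "O", np.array([2.5, 0.0, 0.0]))]
        )
        dense = sasa(frame, [0], n_points=40000)[0]
        errs = [abs(sasa(frame, [0], n_points=n)[0] - dense) for n in (60, 960, 8000)]
        assert errs[2] < errs[0]

    def test_unknown_element_rejected(self):
        frame = make_frame([(1, "HEM", "FE", "FE", np.zeros(3))])
        with pytest.raises(ValueError, match="radius"):
            sasa(frame, [0])

    def test_amide_h_radius(self, helix_llllq):
        frame = helix_llllq.frame(0)
        radii = atom_radii(frame)
        he21 = helix_llllq.atom_index(8, "HE21")
        ha = helix_llllq.atom_index(8, "HA")
        assert radii[he21] == 1.10
        assert radii[ha] == 1.20

    def test_fibonacci_lattice_is_unit_sphere(self):
        pts = fibonacci_sphere(500)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.abs(pts.mean(axis=0)).max() < 0.01


class TestTrajectorySummary:
    def test_all_frames_bonded(self, helix_llllq):
        freq, mean_sasa = trajectory_summary(helix_llllq, 8, 4, n_points=240)
        assert freq == 1.0
        assert mean_sasa >= 0.0

    def test_planted_half_bonded(self):
        bonded = build_ideal_helix(
            "LLLLQQQQQ", -57, -47, rotamers={8: {1: -60, 2: 150, 3: 75}}
        ).frame(0)
        unbonded = build_ideal_helix(
            "LLLLQQQQQ", -57, -47, rotamers={8: {1: 180, 2: 60, 3: 0}}
        ).frame(0)
        ens = Ensemble.from_frames([bonded, unbonded, bonded, unbonded])
        freq, _ = trajectory_summary(ens, 8, 4, n_points=120)
        assert freq == 0.5

    def test_bond_frequency_tracks_sasa_ordering(self):
        """Mixtures with more bonded frames have lower mean He21 exposure."""
        bonded = build_ideal_helix(
            "LLLLQQQQQ", -57, -47, rotamers={8: {1: -60, 2: 150, 3: 75}}
        ).frame(0)
        exposed = build_ideal_helix(
            "LLLLQQQQQ", -57, -47, rotamers={8: {1: 180, 2: 60, 3: 0}}
        ).frame(0)
        stats = []
        for n_bonded in (0, 2, 4):
            frames = [bonded] * n_bonded + [exposed] * (4 - n_bonded)
            stats.append(trajectory_summary(Ensemble.from_frames(frames), 8, 4,
                                            n_points=240))
        freqs = [s[0] for s in stats]
        sasas = [s[1] for s in stats]
        assert freqs == sorted(freqs)
        assert sasas == sorted(sasas, reverse=True)
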
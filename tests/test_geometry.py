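"""Axis fitting, angles, Kabsch superposition, RMSD and H-bond detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.spatial.transform import Rotation

from pentaef.geometry import (HelixAxis, atom_distance, find_hbonds, fit_helix_axis,
                              interhelix_angle, kabsch_superpose, region_rmsd)
from pentaef.structure import AtomRecord, ResidueSelector, Structure
from pentaef.synthetic import HelixSpec, build_helix, helix_ca_coords

from conftest import make_residue


def rot_x(deg):
    return Rotation.from_euler("x", deg, degrees=True).as_matrix()


class TestHelixAxis:
    def test_ideal_helix_axis_along_z(self, ideal_helix_coords):
        ax = fit_helix_axis(ideal_helix_coords)
        assert np.degrees(np.arccos(np.clip(ax.direction @ [0, 0, 1], -1, 1))) < 1e-6

    def test_rotated_helix_recovers_applied_angle(self, ideal_helix_coords):
        rotated = ideal_helix_coords @ rot_x(30.0).T
        ax = fit_helix_axis(rotated)
        angle = np.degrees(np.arccos(np.clip(ax.direction @ [0, 0, 1], -1, 1)))
        assert angle == pytest.approx(30.0, abs=0.01)

    def test_direction_points_n_to_c(self, ideal_helix_coords):
        ax_fwd = fit_helix_axis(ideal_helix_coords)
        ax_rev = fit_helix_axis(ideal_helix_coords[::-1])
        assert np.dot(ax_fwd.direction, ax_rev.direction) == pytest.approx(-1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_helix_axis(np.zeros((3, 3)))

    def test_collinear_points_fit_exactly(self):
        line = np.outer(np.arange(6), [0.0, 0.0, 1.5])
        ax = fit_helix_axis(line)
        assert ax.fit_rms == pytest.approx(0.0, abs=1e-12)

    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_axis_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        coords = helix_ca_coords(HelixSpec(n_residues=10))
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        t = rng.normal(0, 20, 3)
        moved = coords @ R.T + t
        ax0, ax1 = fit_helix_axis(coords), fit_helix_axis(moved)
        np.testing.assert_allclose(ax1.direction, R @ ax0.direction, atol=1e-8)
        assert ax1.fit_rms == pytest.approx(ax0.fit_rms, abs=1e-9)


class TestInterhelixAngle:
    def axis(self, v):
        v = np.asarray(v, float) / np.linalg.norm(v)
        return HelixAxis(direction=v, centroid=np.zeros(3), fit_rms=0.0, n_atoms=4)

    def test_parallel_and_antiparallel(self):
        a = self.axis([0, 0, 1])
        assert interhelix_angle(a, self.axis([0, 0, 1])) == pytest.approx(0.0)
        assert interhelix_angle(a, self.axis([0, 0, -1])) == pytest.approx(180.0)

    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_under_axis_flip(self, seed):
        rng = np.random.default_rng(seed)
        a = self.axis(rng.normal(size=3))
        b_vec = rng.normal(size=3)
        total = interhelix_angle(a, self.axis(b_vec)) + interhelix_angle(a, self.axis(-b_vec))
        assert total == pytest.approx(180.0, abs=1e-9)

    def test_prescribed_angle_between_built_helices(self):
        for theta in (10.0, 50.0, 120.0, 170.0):
            d2 = [0.0, np.sin(np.radians(theta)), np.cos(np.radians(theta))]
            ax1 = fit_helix_axis(helix_ca_coords(HelixSpec()))
            ax2 = fit_helix_axis(helix_ca_coords(HelixSpec(axis_direction=d2)))
            assert interhelix_angle(ax1, ax2) == pytest.approx(theta, abs=0.01)


class TestKabsch:
    def test_identity_case(self, ideal_helix_coords):
        res = kabsch_superpose(ideal_helix_coords, ideal_helix_coords)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_known_transform_recovered(self, ideal_helix_coords, rng):
        R = Rotation.from_euler("zyx", [33.0, -12.0, 71.0], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 12.0])
        target = ideal_helix_coords @ R.T + t
        res = kabsch_superpose(ideal_helix_coords, target)
        assert res.rmsd <= 1e-9
        np.testing.assert_allclose(res.rotation, R, atol=1e-6)
        np.testing.assert_allclose(res.translation, t, atol=1e-6)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_and_degenerate_inputs(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.outer(np.arange(5), [1.0, 0, 0])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)

    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rmsd_invariant_under_pre_rotation(self, seed):
        rng = np.random.default_rng(seed)
        mob = rng.normal(size=(8, 3))
        tgt = rng.normal(size=(8, 3))
        base = kabsch_superpose(mob, tgt).rmsd
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        moved = mob @ R.T + rng.normal(0, 10, 3)
        assert kabsch_superpose(moved, tgt).rmsd == pytest.approx(base, abs=1e-8)

    def test_matches_brute_force_rotation_grid(self, rng):
        """Kabsch RMSD equals the minimum over a dense grid of rotations."""
        mob = rng.normal(size=(6, 3))
        tgt = rng.normal(size=(6, 3))
        res = kabsch_superpose(mob, tgt)
        mob0 = mob - mob.mean(axis=0)
        tgt0 = tgt - tgt.mean(axis=0)
        best = np.inf
        n = 24
        for a in np.linspace(0, 360, n, endpoint=False):
            for b in np.linspace(0, 180, n // 2):
                for c in np.linspace(0, 360, n, endpoint=False):
                    R = Rotation.from_euler("zyz", [a, b, c], degrees=True).as_matrix()
                    d = mob0 @ R.T - tgt0
                    best = min(best, float(np.sqrt(np.mean(np.sum(d**2, axis=1)))))
        assert res.rmsd <= best + 1e-9
        assert best - res.rmsd < 0.3  # grid resolution slack


def two_domain_structures(theta_deg=20.0):
    """Two copies of a two-helix chain; in the second the far helix is rotated."""
    fixed = helix_ca_coords(HelixSpec(n_residues=10))
    moving0 = helix_ca_coords(HelixSpec(n_residues=10, origin=np.array([15.0, 0, 0])))
    pivot = moving0.mean(axis=0)
    moving1 = (moving0 - pivot) @ rot_x(theta_deg).T + pivot

    def build(moving):
        residues = []
        for k, xyz in enumerate(np.vstack([fixed, moving])):
            residues.append(make_residue("A", k + 1, "ALA", [("CA", "C", xyz)]))
        return Structure(entry_id="TD", chains={"A": residues})

    return build(moving0), build(moving1)


class TestRegionRmsd:
    def test_identical_structures_zero_everywhere(self):
        s, _ = two_domain_structures()
        out = region_rmsd(s, s, ResidueSelector("A", 1, 10),
                          [ResidueSelector("A", 11, 20)])
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in out.values())

    def test_rotated_domain_detected_with_bruteforce_value(self):
        a, b = two_domain_structures(theta_deg=20.0)
        out = region_rmsd(a, b, ResidueSelector("A", 1, 10),
                          [ResidueSelector("A", 11, 20)])
        assert out["align"] == pytest.approx(0.0, abs=1e-9)
        # oracle: direct coordinate comparison (alignment region already matches)
        ca = lambda s, lo, hi: np.array(
            [r.atom("CA").coords for r in s.chain("A") if lo <= r.auth_seq_id <= hi])
        diff = ca(a, 11, 20) - ca(b, 11, 20)
        brute = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
        assert out["A:11-20"] == pytest.approx(brute, abs=1e-9)
        assert out["A:11-20"] > 1.0

    def test_disjoint_ranges_error(self):
        a, b = two_domain_structures()
        with pytest.raises(ValueError):
            region_rmsd(a, b, ResidueSelector("A", 100, 110), [])


class TestDistancesAndHbonds:
    def test_atom_distance_pythagoras(self):
        a = AtomRecord("O", "O", np.zeros(3))
        b = AtomRecord("N", "N", np.array([3.0, 4.0, 0.0]))
        assert atom_distance(a, a) == 0.0
        assert atom_distance(a, b) == pytest.approx(5.0)

    def hb_structure(self, d):
        r1 = make_residue("A", 97, "GLU", [("OE2", "O", (0, 0, 0))])
        r2 = make_residue("P", 13, "TYR", [("OH", "O", (d, 0, 0))])
        return Structure(entry_id="HB", chains={"A": [r1], "P": [r2]})

    def test_beyond_cutoff_empty(self):
        assert find_hbonds(self.hb_structure(5.0), cutoff=3.5) == []

    def test_planted_pair_detected_at_its_distance(self):
        bonds = find_hbonds(self.hb_structure(2.8), cutoff=3.5)
        # the O...O pair appears once per direction assignment; distances agree
        assert bonds and all(b.distance == pytest.approx(2.8) for b in bonds)
        pairs = {frozenset([b.donor_residue.key, b.acceptor_residue.key]) for b in bonds}
        assert pairs == {frozenset([("A", 97, ""), ("P", 13, "")])}

    def test_sorted_by_distance_and_same_residue_excluded(self):
        r = make_residue("A", 1, "SER", [("N", "N", (0, 0, 0)), ("OG", "O", (1.4, 0, 0))])
        r2 = make_residue("A", 2, "SER", [("OG", "O", (3.0, 0, 0))])
        r3 = make_residue("A", 3, "SER", [("OG", "O", (2.0, 0, 0))])
        s = Structure(entry_id="S", chains={"A": [r, r2, r3]})
        bonds = find_hbonds(s, cutoff=3.5)
        dists = [b.distance for b in bonds]
        assert dists == sorted(dists)
        assert all(b.donor_residue.key != b.acceptor_residue.key for b in bonds)
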
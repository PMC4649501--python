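"""SASA computation, ΔSASA filtering, hydrophobic patches and interface burial."""

import numpy as np
import pytest

from pentaef.structure import AtomRecord, Residue, Structure
from pentaef.surface import (MAX_SASA, SasaProfile, VDW_RADII, compute_sasa, delta_sasa,
                             hydrophobic_patches, interface_burial, sasa_points)

from conftest import make_residue


def lone_atom_structure(element="C"):
    res = make_residue("A", 1, "ALA", [("CA", element, (0.0, 0.0, 0.0))])
    return Structure(entry_id="ONE", chains={"A": [res]})


def two_sphere_analytic(r1, r2, d):
    """Total accessible area of two intersecting spheres (spherical caps)."""
    if d >= r1 + r2:
        return 4 * np.pi * (r1**2 + r2**2)
    x1 = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    x2 = d - x1
    a1 = 4 * np.pi * r1**2 - 2 * np.pi * r1 * (r1 - x1)
    a2 = 4 * np.pi * r2**2 - 2 * np.pi * r2 * (r2 - x2)
    return a1 + a2


class TestComputeSasa:
    def test_lone_carbon_matches_analytic_sphere(self):
        prof = compute_sasa(lone_atom_structure(), n_points=960)
        expected = 4 * np.pi * (VDW_RADII["C"] + 1.4) ** 2  # ~120.76 A^2
        assert prof.get("A", 1) == pytest.approx(expected, rel=0.005)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_spheres_match_cap_formula(self, d):
        r = VDW_RADII["C"] + 1.4
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas = sasa_points(coords, np.array([1.7, 1.7]), probe=1.4, n_points=960)
        assert areas.sum() == pytest.approx(two_sphere_analytic(r, r, d), rel=0.02)

    def test_buried_atom_in_cage_has_zero_sasa(self):
        # caged atom surrounded by a dense shell of occluders
        pts = []
        n = 200
        i = np.arange(n) + 0.5
        phi = np.pi * (3 - np.sqrt(5)) * i
        z = 1 - 2 * i / n
        rr = np.sqrt(1 - z * z)
        shell = 2.2 * np.column_stack([rr * np.cos(phi), rr * np.sin(phi), z])
        atoms = [("C1", "C", (0.0, 0.0, 0.0))]
        atoms += [(f"C{k+2}", "C", tuple(p)) for k, p in enumerate(shell)]
        res = Residue(chain_id="A", auth_seq_id=1, res_name="UNK")
        for name, el, xyz in atoms:
            res.add_atom(AtomRecord(name, el, np.asarray(xyz)))
        s = Structure(entry_id="CAGE", chains={"A": [res]})
        prof = compute_sasa(s, n_points=500)
        assert prof.atom_sasa[("A", 1, "C1")] == 0.0

    def test_point_count_convergence(self):
        coords = np.array([[0.0, 0, 0], [2.0, 1.0, 0], [0.5, -1.5, 1.0]])
        radii = np.array([1.7, 1.55, 1.52])
        a_lo = sasa_points(coords, radii, 1.4, 960).sum()
        a_hi = sasa_points(coords, radii, 1.4, 4000).sum()
        assert abs(a_lo - a_hi) / a_hi < 0.01

    def test_waters_and_ions_excluded_by_default(self):
        protein = make_residue("A", 1, "ALA", [("CA", "C", (0, 0, 0))])
        water = make_residue("A", 101, "HOH", [("O", "O", (2.0, 0, 0), True)])
        ion = make_residue("A", 201, "CA", [("CA", "CA", (-2.0, 0, 0), True)])
        s = Structure(entry_id="W", chains={"A": [protein, water, ion]})
        prof = compute_sasa(s)
        lone = compute_sasa(lone_atom_structure())
        assert prof.get("A", 1) == pytest.approx(lone.get("A", 1))
        assert prof.get("A", 101) is None and prof.get("A", 201) is None

    def test_empty_structure_and_bad_params(self):
        s = Structure(entry_id="E", chains={"A": [make_residue("A", 1, "HOH",
                                                               [("O", "O", (0, 0, 0), True)])]})
        with pytest.raises(ValueError):
            compute_sasa(s)
        with pytest.raises(ValueError):
            compute_sasa(lone_atom_structure(), probe=-1)
        with pytest.raises(ValueError):
            compute_sasa(lone_atom_structure(), n_points=50)


class TestBiotiteOracle:
    def test_agreement_with_independent_shrake_rupley(self):
        """Per-atom agreement with biotite's Shrake–Rupley on a random cluster,
        using one shared radii table so only the sampling machinery differs."""
        biotite_struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(4)
        n = 40
        coords = rng.normal(scale=4.0, size=(n, 3))
        radii = rng.choice([1.52, 1.55, 1.7, 1.8], size=n)
        mine = sasa_points(coords, radii, probe=1.4, n_points=3000)

        arr = biotite_struc.AtomArray(n)
        arr.coord = coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, n + 1)
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        theirs = biotite_struc.sasa(arr, probe_radius=1.4, point_number=3000,
                                    vdw_radii=radii.astype(float))
        total_mine, total_theirs = mine.sum(), theirs.sum()
        assert total_mine == pytest.approx(total_theirs, rel=0.02)
        # per-atom: within 2% of the per-atom scale (exposed atoms)
        scale = np.maximum(theirs, 1.0)
        assert np.max(np.abs(mine - theirs) / scale) < 0.05


def profile(d, **kw):
    return SasaProfile(residue_sasa=d, probe_radius=1.4, n_points=960, **kw)


class TestDeltaSasa:
    def test_identical_profiles_nothing_flagged(self):
        p = profile({("A", 1): 50.0, ("A", 2): 10.0})
        rep = delta_sasa(p, p)
        assert rep.flagged == []

    def test_doubling_residue_flagged_at_plus_100pct(self):
        apo = profile({("A", 1): 10.0, ("A", 2): 40.0})
        holo = profile({("A", 1): 20.0, ("A", 2): 40.0})
        rep = delta_sasa(apo, holo)
        assert rep.flagged == [("A", 1)]
        row = next(r for r in rep.rows if r["auth_seq_id"] == 1)
        assert row["relative_change_pct"] == pytest.approx(100.0)

    def test_absolute_increase_guard(self):
        # +200% but only +2 A^2: tiny denominators must not dominate
        apo = profile({("A", 1): 1.0})
        holo = profile({("A", 1): 3.0})
        assert delta_sasa(apo, holo).flagged == []

    def test_denominator_floor_for_fully_buried(self):
        apo = profile({("A", 1): 0.0})
        holo = profile({("A", 1): 8.0})
        rep = delta_sasa(apo, holo)
        assert rep.rows[0]["relative_change_pct"] == pytest.approx(800.0)
        assert rep.flagged == [("A", 1)]

    def test_sign_antisymmetry_under_profile_swap(self):
        apo = profile({("A", 1): 20.0})
        holo = profile({("A", 1): 30.0})
        fwd = delta_sasa(apo, holo).rows[0]["relative_change_pct"]
        rev = delta_sasa(holo, apo).rows[0]["relative_change_pct"]
        # antisymmetric up to the denominator convention (apo in both cases)
        assert fwd == pytest.approx(50.0) and rev == pytest.approx(-100.0 / 3.0)
        assert np.sign(fwd) == -np.sign(rev)

    def test_disjoint_profiles_error(self):
        with pytest.raises(ValueError):
            delta_sasa(profile({("A", 1): 1.0}), profile({("B", 9): 1.0}))


def residue_at(chain, seq, name, xyz):
    return make_residue(chain, seq, name, [("CA", "C", xyz), ("CB", "C", np.add(xyz, (0, 0, 1.5)))])


class TestHydrophobicPatches:
    def test_three_close_exposed_leucines_one_patch(self):
        residues = [
            residue_at("A", 1, "LEU", (0, 0, 0)),
            residue_at("A", 2, "LEU", (5.0, 0, 0)),
            residue_at("A", 3, "LEU", (2.5, 4.0, 0)),
            residue_at("A", 10, "SER", (20.0, 0, 0)),  # polar: never a member
        ]
        s = Structure(entry_id="P", chains={"A": residues})
        sasa = compute_sasa(s, n_points=500)
        patches = hydrophobic_patches(s, sasa, linkage=6.5)
        assert len(patches) == 1
        assert patches[0].residue_keys() == {("A", 1), ("A", 2), ("A", 3)}

    def test_buried_residues_excluded(self):
        residues = [residue_at("A", 1, "LEU", (0, 0, 0))]
        s = Structure(entry_id="B", chains={"A": residues})
        buried = profile({("A", 1): 0.1 * MAX_SASA["L"]})  # below 20% exposure
        assert hydrophobic_patches(s, buried) == []

    def test_singletons_dropped_and_ranking_by_area(self):
        residues = [
            residue_at("A", 1, "TRP", (0, 0, 0)),
            residue_at("A", 2, "TRP", (5, 0, 0)),
            residue_at("A", 3, "ALA", (40, 0, 0)),
            residue_at("A", 4, "ALA", (44, 0, 0)),
            residue_at("A", 9, "MET", (100, 0, 0)),  # isolated singleton
        ]
        s = Structure(entry_id="R", chains={"A": residues})
        sasa = compute_sasa(s, n_points=500)
        patches = hydrophobic_patches(s, sasa, linkage=6.5)
        assert len(patches) == 2
        assert patches[0].rank == 1
        assert patches[0].total_exposed_area >= patches[1].total_exposed_area
        assert all(("A", 9) not in p.residue_keys() for p in patches)

    def test_membership_invariant_under_residue_order(self):
        residues = [
            residue_at("A", 1, "LEU", (0, 0, 0)),
            residue_at("A", 2, "LEU", (5.0, 0, 0)),
            residue_at("A", 5, "PHE", (30, 0, 0)),
            residue_at("A", 6, "PHE", (34, 0, 0)),
        ]
        s1 = Structure(entry_id="O1", chains={"A": residues})
        s2 = Structure(entry_id="O2", chains={"A": residues[::-1]})
        sets1 = {frozenset(p.residue_keys()) for p in
                 hydrophobic_patches(s1, compute_sasa(s1, n_points=500))}
        sets2 = {frozenset(p.residue_keys()) for p in
                 hydrophobic_patches(s2, compute_sasa(s2, n_points=500))}
        assert sets1 == sets2


class TestInterfaceBurial:
    def chains_apart(self, gap):
        a = make_residue("A", 1, "ALA", [("CA", "C", (0, 0, 0))])
        b = make_residue("B", 1, "ALA", [("CA", "C", (gap, 0, 0))])
        return Structure(entry_id="IF", chains={"A": [a], "B": [b]})

    def test_distant_chains_empty_interface(self):
        rep = interface_burial(self.chains_apart(25.0), {"A"}, {"B"})
        assert rep.total_buried_area == 0.0
        assert rep.buried_keys() == set()

    def test_touching_atoms_match_two_run_oracle(self):
        s = self.chains_apart(4.0)
        rep = interface_burial(s, {"A"}, {"B"}, n_points=960)
        iso = compute_sasa(Structure(entry_id="x", chains={"A": s.chains["A"]}), n_points=960)
        cplx = compute_sasa(s, n_points=960)
        oracle = iso.get("A", 1) - cplx.get("A", 1)
        assert rep.buried_a[("A", 1)] == pytest.approx(oracle)

    def test_additivity_bound_and_factor_two(self):
        s = self.chains_apart(4.0)
        cplx = compute_sasa(s, n_points=960).total()
        iso_a = compute_sasa(Structure(entry_id="a", chains={"A": s.chains["A"]}), n_points=960).total()
        iso_b = compute_sasa(Structure(entry_id="b", chains={"B": s.chains["B"]}), n_points=960).total()
        rep = interface_burial(s, {"A"}, {"B"}, n_points=960)
        assert cplx <= iso_a + iso_b
        assert (iso_a + iso_b - cplx) == pytest.approx(rep.total_buried_area, abs=1e-6)

    def test_overlapping_partners_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            interface_burial(self.chains_apart(4.0), {"A"}, {"A"})
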
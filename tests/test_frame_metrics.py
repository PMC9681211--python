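"""Dyad detection, canonical framing, radius of gyration, lobes, hinge bend."""
import numpy as np
import pytest

from mabstitch.errors import GeometryError, SelectionError, SymmetryError
from mabstitch.fixtures import make_c2_dimer, make_ideal_peptide, perturb
from mabstitch.frame import (
    canonical_frame,
    compute_dyad,
    hinge_bend_angle,
    lobe_extent,
    radius_of_gyration,
)
from mabstitch.geometry import random_rigid_transform
from mabstitch.model import Atom, Chain, Residue, Structure


def _dimer(axis=(0, 0, 1.0), point=(0, 0, 0)):
    mono = make_ideal_peptide("ACDEFGPK", chain_id="H")
    return make_c2_dimer(mono, axis=axis, point=point)


def _cas(chain):
    return np.array([r.atom("CA").coords for r in chain.residues])


class TestDyad:
    def test_exact_c2_about_z(self):
        dim = _dimer()
        d = compute_dyad(_cas(dim.chains[0]), _cas(dim.chains[1]))
        assert d.rotation_angle == pytest.approx(180.0, abs=1e-9)
        assert abs(abs(d.direction[2]) - 1.0) < 1e-9

    def test_noisy_dimer_recovers_axis_within_a_degree(self):
        dim = perturb(_dimer(), 0.1, 5)
        d = compute_dyad(_cas(dim.chains[0]), _cas(dim.chains[1]))
        angle_to_z = np.degrees(np.arccos(min(1.0, abs(d.direction[2]))))
        assert angle_to_z < 1.0

    def test_unrelated_coordinates_raise_symmetry_error(self):
        a = _cas(make_ideal_peptide("ACDEFGHI").chains[0])
        b = _cas(make_ideal_peptide("ACDEFGHI", "helical").chains[0])
        with pytest.raises(SymmetryError):
            compute_dyad(a, b)

    def test_axis_line_symmetric_in_argument_order(self):
        dim = _dimer(axis=(1, 1, 0) / np.sqrt(2), point=(2, -1, 0))
        a, b = _cas(dim.chains[0]), _cas(dim.chains[1])
        d1 = compute_dyad(a, b)
        d2 = compute_dyad(b, a)
        assert abs(abs(d1.direction @ d2.direction) - 1.0) < 1e-9
        assert np.abs(d1.point - d2.point).max() < 1e-6


class TestCanonicalFrame:
    FC = [("H", (1, 8)), ("h", (1, 8))]
    FAB = [("H", (1, 3))]
    PRO = (("H", 7), ("h", 7))

    def test_recovers_known_rigid_motion(self):
        dim = _dimer()
        dyad0 = compute_dyad(_cas(dim.chains[0]), _cas(dim.chains[1]))
        _, canon = canonical_frame(dim, dyad0, self.PRO, self.FC, self.FAB)
        tr = random_rigid_transform(np.random.default_rng(2))
        moved = tr.transform_structure(canon)
        dyad = compute_dyad(_cas(moved.chains[0]), _cas(moved.chains[1]))
        _, back = canonical_frame(moved, dyad, self.PRO, self.FC, self.FAB)
        assert np.abs(back.coords() - canon.coords()).max() < 1e-8

    def test_origin_and_orientation_conventions(self):
        dim = _dimer(axis=(0, 1, 1) / np.sqrt(2), point=(3, 1, -2))
        dyad = compute_dyad(_cas(dim.chains[0]), _cas(dim.chains[1]))
        _, canon = canonical_frame(dim, dyad, self.PRO, self.FC, self.FAB)
        mid = 0.5 * (
            canon.chain("H").residue(7).atom("CA").coords
            + canon.chain("h").residue(7).atom("CA").coords
        )
        assert np.abs(mid).max() < 1e-6
        w = canon.masses()
        com = (w[:, None] * canon.coords()).sum(axis=0) / w.sum()
        assert com[2] < 0  # body below the xy plane

    def test_idempotent(self):
        dim = _dimer(axis=(1, 0, 1) / np.sqrt(2), point=(1, 2, 3))
        dyad = compute_dyad(_cas(dim.chains[0]), _cas(dim.chains[1]))
        _, once = canonical_frame(dim, dyad, self.PRO, self.FC, self.FAB)
        dyad2 = compute_dyad(_cas(once.chains[0]), _cas(once.chains[1]))
        tr2, twice = canonical_frame(once, dyad2, self.PRO, self.FC, self.FAB)
        assert tr2.is_identity(1e-8)
        assert np.abs(twice.coords() - once.coords()).max() < 1e-8


class TestRadiusOfGyration:
    def _point_structure(self, coords, element="C"):
        chain = Chain("A")
        for i, xyz in enumerate(coords):
            chain.residues.append(
                Residue("GLY", i + 1, atoms=[Atom(i + 1, "CA", element, xyz)])
            )
        return Structure(chains=[chain])

    def test_single_atom_is_zero(self):
        assert radius_of_gyration(self._point_structure([[1.0, 2, 3]])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_unit_mass_atoms_two_angstrom_apart(self):
        s = self._point_structure([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(s, "uniform") == pytest.approx(0.1)

    def test_invariant_under_rigid_motion_and_order(self, small_peptide):
        rg = radius_of_gyration(small_peptide)
        tr = random_rigid_transform(np.random.default_rng(1))
        assert radius_of_gyration(tr.transform_structure(small_peptide)) == pytest.approx(
            rg, abs=1e-9
        )
        shuffled = small_peptide.copy()
        shuffled.chains[0].residues.reverse()
        for i, r in enumerate(shuffled.chains[0].residues):
            r.seq_num = i + 1
        assert radius_of_gyration(shuffled) == pytest.approx(rg, abs=1e-12)

    def test_mass_weighting_differs_from_uniform(self):
        s = make_ideal_peptide("GW")
        assert radius_of_gyration(s, "mass") != pytest.approx(
            radius_of_gyration(s, "uniform"), abs=1e-6
        )


class TestLobes:
    def test_single_atom_lobe_extent(self):
        s = TestRadiusOfGyration()._point_structure([[0.0, 0, 30.0]])
        out = lobe_extent(s, {"fab1": [("A", (1, 1))]})
        assert out["fab1"] == pytest.approx(3.0)

    def test_matches_brute_force_scan(self, small_peptide):
        out = lobe_extent(small_peptide, {"all": [("A", (1, 5))]})
        brute = max(np.linalg.norm(small_peptide.coords(), axis=1)) / 10.0
        assert out["all"] == pytest.approx(brute)

    def test_empty_selection_is_an_error(self, small_peptide):
        with pytest.raises(SelectionError):
            lobe_extent(small_peptide, {"fc": [("A", (90, 99))]})


class TestHingeBend:
    def _ca_path(self, points):
        chain = Chain("A")
        for i, xyz in enumerate(points):
            chain.residues.append(
                Residue("GLY", i + 1, atoms=[Atom(i + 1, "CA", "C", xyz)])
            )
        return Structure(chains=[chain])

    def test_straight_window_is_near_180(self):
        s = make_ideal_peptide("GAGAGAGAGA")
        angle = hinge_bend_angle(s, "A", list(range(1, 11)))
        assert angle > 170.0

    def test_right_angle_path(self):
        pts = [[i, 0.0, 0.0] for i in range(4)] + [[3.0, i, 0.0] for i in range(1, 5)]
        s = self._ca_path(np.array(pts, dtype=float))
        angle = hinge_bend_angle(s, "A", list(range(1, 9)))
        assert angle == pytest.approx(90.0, abs=1.0)

    def test_missing_ca_is_an_error(self):
        s = make_ideal_peptide("GAGAG")
        s.chain("A").residue(3).remove_atom("CA")
        with pytest.raises(GeometryError):
            hinge_bend_angle(s, "A", [1, 2, 3, 4, 5])
        with pytest.raises(GeometryError):
            hinge_bend_angle(s, "A", [1, 2, 4, 5])  # fewer than 3 CA per half
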
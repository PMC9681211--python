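"""Surrogate force field and the staged SD/CG minimizer."""
import numpy as np
import pytest

from mabstitch.assembly import add_hydrogens, splice, SpliceSpec
from mabstitch.bondgraph import covalent_bonds
from mabstitch.errors import MinimizationError
from mabstitch.fixtures import make_ideal_peptide, make_paired_hinge, perturb
from mabstitch.forcefield import (
    BOND_K,
    build_topology,
    energy_and_gradient,
    minimize,
    minimize_function,
)
from mabstitch.geometry import random_rigid_transform
from mabstitch.templates import residue_template


class TestTopology:
    def test_single_glycine_bond_count(self):
        ff = build_topology(make_ideal_peptide("G"))
        assert len(ff.bond_idx) == 3  # N-CA, CA-C, C-O

    def test_dipeptide_has_exactly_one_interresidue_bond(self):
        s = make_ideal_peptide("GG")
        bonds = covalent_bonds(s)
        inter = [b for b in bonds if b[2] == "peptide"]
        assert len(inter) == 1
        assert (inter[0][0].atom_name, inter[0][1].atom_name) == ("C", "N")

    def test_paired_hinge_bonds_are_templates_plus_two_disulfides(self, paired_hinge):
        n_template = 0
        for chain in paired_hinge.chains:
            for res in chain.residues:
                t = residue_template(res.name)
                present = set(res.atom_names())
                n_template += sum(1 for a, b in t.bonds if a in present and b in present)
        n_peptide = sum(len(c.residues) - 1 for c in paired_hinge.chains)
        assert len(covalent_bonds(paired_hinge)) == n_template + n_peptide + 2


class TestEnergy:
    def test_ideal_fixture_is_at_the_minimum(self):
        s = add_hydrogens(make_ideal_peptide("GAG", cterm_carboxyl=True))
        ff = build_topology(s)
        e, g = energy_and_gradient(s, ff)
        assert e < 1e-10
        assert np.abs(g).max() < 1e-4

    def test_stretched_bond_closed_form(self):
        s = make_ideal_peptide("G")
        ff = build_topology(s)
        ff.sigma[:] = 0.0
        ff.angle_k[:] = 0.0
        delta = 0.07
        stretched = s.copy()
        n = stretched.chains[0].residues[0].atom("N")
        ca = stretched.chains[0].residues[0].atom("CA")
        direction = (n.coords - ca.coords) / np.linalg.norm(n.coords - ca.coords)
        n.coords = n.coords + delta * direction
        e, g = energy_and_gradient(stretched, ff)
        assert e == pytest.approx(BOND_K * delta**2, rel=1e-9)
        assert np.linalg.norm(g[0]) == pytest.approx(2 * BOND_K * delta, rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_analytic_gradient_matches_finite_differences(self, seed):
        s = add_hydrogens(make_ideal_peptide("ACSG"))
        ff = build_topology(s)
        sp = perturb(s, 0.08, seed)
        x = sp.coords().ravel()
        _, g = ff.energy_gradient(x)
        rng = np.random.default_rng(seed)
        for i in rng.choice(len(x), size=8, replace=False):
            h = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (ff.energy_gradient(xp)[0] - ff.energy_gradient(xm)[0]) / (2 * h)
            assert fd == pytest.approx(g[i], rel=1e-5, abs=1e-7)


class TestMinimize:
    def test_already_minimal_trace_is_constant_zero(self):
        s = make_ideal_peptide("GAG")
        ff = build_topology(s)
        out, trace = minimize(s, ff, 10, 10)
        assert len(trace) == 20
        assert np.all(trace.energies < 1e-10)
        assert np.abs(out.coords() - s.coords()).max() < 1e-6

    def test_cg_solves_quadratic_in_dim_iterations(self):
        # CG terminates in at most as many iterations as distinct eigenvalues
        rng = np.random.default_rng(6)
        dim = 15
        Q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
        vals = np.array([2.0, 5.0, 11.0, 23.0])[rng.integers(0, 4, size=dim)]
        A = Q @ np.diag(vals) @ Q.T
        b = rng.normal(size=dim)

        def fgrad(x):
            return 0.5 * x @ A @ x - b @ x, A @ x - b

        x, trace = minimize_function(np.zeros(dim), fgrad, n_sd=0, n_cg=dim)
        assert trace.max_gradients[-1] < 1e-8
        assert np.abs(x - np.linalg.solve(A, b)).max() < 1e-8

    def test_trace_has_exactly_the_requested_length(self):
        s = perturb(make_ideal_peptide("GAGA"), 0.1, 2)
        ff = build_topology(s)
        _, trace = minimize(s, ff, 12, 7)
        assert len(trace) == 19
        phases = [p for _, p, _, _ in trace.steps]
        assert phases[:12] == ["SD"] * 12 and phases[12:] == ["CG"] * 7

    def test_energy_monotone_and_identity_preserved(self):
        s = add_hydrogens(make_ideal_peptide("GACG"))
        sp = perturb(s, 0.25, 11)
        ff = build_topology(sp)
        out, trace = minimize(sp, ff, 40, 40)
        assert np.all(np.diff(trace.energies) <= 1e-9)
        assert trace.max_gradients[-1] <= trace.max_gradients[0]
        assert out.n_atoms() == sp.n_atoms()
        # CA chirality (L-amino acids) preserved
        for chain_in, chain_out in zip(sp.chains, out.chains):
            for r_in, r_out in zip(chain_in.residues, chain_out.residues):
                if r_in.has_atom("CB"):
                    assert _chirality(r_in) == _chirality(r_out)

    def test_non_finite_energy_reported(self):
        def fgrad(x):
            return float("nan"), x

        with pytest.raises(MinimizationError):
            minimize_function(np.ones(3), fgrad, 1, 0)


def _chirality(res):
    n = res.atom("N").coords - res.atom("CA").coords
    c = res.atom("C").coords - res.atom("CA").coords
    cb = res.atom("CB").coords - res.atom("CA").coords
    return np.sign(np.dot(np.cross(n, c), cb))


class TestJunctionGeometry:
    def test_spliced_bond_restored_by_minimization(self):
        s = make_ideal_peptide("GAVKKAGAV")
        moved = s.copy()
        tr = random_rigid_transform(np.random.default_rng(13), max_translation=5.0)
        for r in moved.chain("A").residues:
            if r.seq_num >= 5:
                for a in r.atoms:
                    a.coords = tr.apply(a.coords[None, :])[0]
        spliced = splice(moved, SpliceSpec(chain_ids=["A"], anchor=4, downstream_first=5))
        ff = build_topology(spliced)
        out, _ = minimize(spliced, ff, 150, 150)
        chain = out.chain("A")
        for i in range(len(chain.residues) - 1):
            d = np.linalg.norm(
                chain.residues[i].atom("C").coords - chain.residues[i + 1].atom("N").coords
            )
            assert d == pytest.approx(1.33, abs=0.05)

    def test_disulfide_geometry_after_minimization(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = make_paired_hinge(flank_n="G", flank_c="G")
        hp = perturb(h, 0.15, 21)
        ff = build_topology(hp)
        out, _ = minimize(hp, ff, 120, 120)
        for num in (2, 5):
            d = np.linalg.norm(
                out.chain("A").residue(num).atom("SG").coords
                - out.chain("B").residue(num).atom("SG").coords
            )
            assert d == pytest.approx(2.05, abs=0.1)
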
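"""Edit scripts, splicing, mutation, terminus completion, disulfides,
hydrogen addition and the five-part graft."""
import numpy as np
import pytest

from mabstitch.assembly import (
    EditOp,
    EditScript,
    SpliceSpec,
    add_hydrogens,
    apply_edit_script,
    assemble,
    extend_terminus,
    mutate_residue,
    set_disulfide,
    splice,
)
from mabstitch.errors import ChemistryError, GeometryError, ScriptError
from mabstitch.fixtures import make_five_part_plan, make_ideal_peptide
from mabstitch.geometry import random_rigid_transform
from mabstitch.model import ONE_TO_THREE
from mabstitch.templates import residue_template


class TestEditScript:
    def test_empty_script_is_identity(self, small_peptide):
        out = apply_edit_script(small_peptide, EditScript("A", []))
        assert out.chain("A").sequence() == small_peptide.chain("A").sequence()
        assert np.array_equal(out.coords(), small_peptide.coords())

    def test_deleting_two_residues_from_hinge(self):
        # 27-residue donor hinge; removing the two surplus residues (KC)
        hinge = make_ideal_peptide("ELLGGPSVFKCPAPELLGGPSVFLFPP")
        assert len(hinge.chains[0].residues) == 27
        out = apply_edit_script(
            hinge, EditScript("A", [EditOp("delete", 10, 11)])
        )
        assert len(out.chains[0].residues) == 25
        assert "KC" not in out.chain("A").sequence()[8:12]

    def test_missing_residue_reported(self, small_peptide):
        with pytest.raises(ScriptError):
            apply_edit_script(small_peptide, EditScript("A", [EditOp("delete", 99)]))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_scripts_match_string_edit_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        seq = "".join(rng.choice(letters, size=14))
        s = make_ideal_peptide(seq)
        expected = list(seq)
        ops = []
        nums = list(range(1, 15))
        for _ in range(3):
            if rng.random() < 0.5 and len(nums) > 2:
                k = int(rng.choice(nums))
                ops.append(EditOp("delete", k))
                expected[k - 1] = None
                nums.remove(k)
            else:
                k = int(rng.choice(nums))
                aa = str(rng.choice(letters))
                ops.append(EditOp("substitute", k, new_aa=aa))
                expected[k - 1] = aa
        out = apply_edit_script(s, EditScript("A", ops))
        assert out.chain("A").sequence() == "".join(a for a in expected if a)


class TestSplice:
    def test_downstream_lands_on_anchor_frame(self):
        # anchor K4 and downstream K5 share a template, so the splice must
        # put the downstream backbone exactly onto the recorded frame
        s = make_ideal_peptide("GAVKKAG")
        anchor_frame = np.array(
            [s.chain("A").residue(4).atom(a).coords for a in ("N", "CA", "C")]
        )
        moved = s.copy()
        tr = random_rigid_transform(np.random.default_rng(8))
        for r in moved.chain("A").residues:
            if r.seq_num >= 5:
                for a in r.atoms:
                    a.coords = tr.apply(a.coords[None, :])[0]
        out = splice(moved, SpliceSpec(chain_ids=["A"], anchor=4, downstream_first=5))
        new_frame = np.array(
            [out.chain("A").residue(4).atom(a).coords for a in ("N", "CA", "C")]
        )
        assert np.abs(new_frame - anchor_frame).max() < 1e-6

    def test_intervening_residues_removed_and_renumbered(self):
        s = make_ideal_peptide("GAVKCPAG")  # remove KC, pull P onto K
        out = splice(s, SpliceSpec(chain_ids=["A"], anchor=4, downstream_first=6))
        assert out.chain("A").sequence() == "GAVPAG"
        assert [r.seq_num for r in out.chain("A").residues] == [1, 2, 3, 4, 5, 6]

    def test_missing_backbone_is_a_splice_error(self):
        from mabstitch.errors import SpliceError

        s = make_ideal_peptide("GAVKCPAG")
        s.chain("A").residue(6).remove_atom("CA")
        with pytest.raises(SpliceError):
            splice(s, SpliceSpec(chain_ids=["A"], anchor=4, downstream_first=6))


class TestMutate:
    def test_ala_to_gly_loses_exactly_cb(self):
        s = add_hydrogens(make_ideal_peptide("GAG"))
        before = s.chain("A").residue(2)
        n_h_before = sum(1 for a in before.atoms if a.element == "H")
        out = mutate_residue(s, "A", 2, "G")
        res = out.chain("A").residue(2)
        assert not res.has_atom("CB")
        assert len(res.heavy_atoms()) == len(before.heavy_atoms()) - 1
        # methyl hydrogens gone, two glycine HA present
        assert sum(1 for a in res.atoms if a.element == "H") == n_h_before - 2

    def test_ser_to_ala_heavy_atom_difference(self):
        s = make_ideal_peptide("GSG")
        out = mutate_residue(s, "A", 2, "A")
        assert len(out.chain("A").residue(2).heavy_atoms()) == len(
            s.chain("A").residue(2).heavy_atoms()
        ) - 1  # OG removed

    def test_lys_to_arg_rebuilds_ideal_side_chain(self):
        s = make_ideal_peptide("GAKAG", "helical")
        out = mutate_residue(s, "A", 3, "R")
        res = out.chain("A").residue(3)
        t = residue_template("ARG")
        for a, b in t.bonds:
            if res.has_atom(a) and res.has_atom(b):
                d = np.linalg.norm(res.atom(a).coords - res.atom(b).coords)
                d0 = np.linalg.norm(t.coords[a] - t.coords[b])
                assert abs(d - d0) < 0.02

    def test_unknown_target_rejected(self, small_peptide):
        with pytest.raises(ChemistryError):
            mutate_residue(small_peptide, "A", 2, "B")


class TestExtendTerminus:
    def test_empty_extension_is_noop(self, small_peptide):
        out = extend_terminus(small_peptide, "A", "", "C")
        assert np.array_equal(out.coords(), small_peptide.coords())

    def test_c_terminal_completion_reaches_full_length(self):
        # a chain ending at 447 gains its three missing residues -> 450
        s = make_ideal_peptide("GAVL", start_num=444)
        out = extend_terminus(s, "A", "PGK", "C")
        nums = [r.seq_num for r in out.chain("A").residues]
        assert nums[-1] == 450
        assert len(nums) == 7

    def test_new_peptide_bonds_are_ideal(self):
        s = make_ideal_peptide("GAVL")
        out = extend_terminus(s, "A", "PGK", "C")
        chain = out.chain("A")
        for i in range(len(chain.residues) - 1):
            d = np.linalg.norm(
                chain.residues[i].atom("C").coords - chain.residues[i + 1].atom("N").coords
            )
            assert d == pytest.approx(1.33, abs=0.01)

    def test_n_terminal_extension(self):
        s = make_ideal_peptide("GAVL", start_num=4)
        out = extend_terminus(s, "A", "KPT", "N")
        assert out.chain("A").sequence() == "KPTGAVL"
        assert [r.seq_num for r in out.chain("A").residues][0] == 1


class TestDisulfide:
    def test_form_then_remove_restores_structure(self, paired_hinge):
        s = add_hydrogens(paired_hinge)
        broken = set_disulfide(s, ("A", 1), ("B", 1), present=False)
        assert len(broken.find_links("disulfide")) == 1
        assert broken.chain("A").residue(1).has_atom("HG")
        reformed = set_disulfide(broken, ("A", 1), ("B", 1), present=True)
        assert len(reformed.find_links("disulfide")) == 2
        assert not reformed.chain("A").residue(1).has_atom("HG")
        assert reformed.n_atoms() == s.n_atoms()

    def test_forming_on_non_cys_is_an_error(self, small_peptide):
        with pytest.raises(ChemistryError):
            set_disulfide(small_peptide, ("A", 1), ("A", 2), present=True)

    def test_distant_sulfurs_rejected(self):
        s = make_ideal_peptide("CAAAAAAAAC")  # extended: SG-SG far apart
        with pytest.raises(GeometryError):
            set_disulfide(s, ("A", 1), ("A", 10), present=True)


class TestHydrogens:
    def test_internal_alanine_gains_five_hydrogens(self):
        s = add_hydrogens(make_ideal_peptide("GAG"))
        res = s.chain("A").residue(2)
        hs = sorted(a.name for a in res.atoms if a.element == "H")
        assert hs == ["H", "HA", "HB1", "HB2", "HB3"]

    def test_cystine_pair_has_no_hg(self, paired_hinge):
        s = add_hydrogens(paired_hinge)
        for cid in ("A", "B"):
            for num in (1, 4):
                assert not s.chain(cid).residue(num).has_atom("HG")

    def test_proline_has_no_amide_hydrogen(self):
        s = add_hydrogens(make_ideal_peptide("GPG"))
        assert not s.chain("A").residue(2).has_atom("H")

    def test_hydrogen_bond_lengths_near_ideal(self):
        from mabstitch.bondgraph import covalent_bonds

        s = add_hydrogens(make_ideal_peptide("ASNQW", cterm_carboxyl=True))
        for a, b, kind in covalent_bonds(s):
            pa, pb = s.atom(a), s.atom(b)
            if "H" in (pa.element, pb.element):
                d = np.linalg.norm(pa.coords - pb.coords)
                assert 0.85 < d < 1.15


class TestAssemble:
    def test_atom_conservation(self):
        plan, truth = make_five_part_plan(2)
        out = assemble(plan)
        assert out.n_atoms() == truth.n_atoms()
        assert [c.id for c in out.chains] == ["H", "L", "V", "M"]

    def test_incompatible_junction_detected(self):
        from mabstitch.errors import AssemblyError
        from mabstitch.fixtures import perturb

        plan, _ = make_five_part_plan(3)
        bad = plan.part("fc")
        bad.structure = perturb(bad.structure, 3.0, 1)  # wreck the junction
        with pytest.raises(AssemblyError):
            assemble(plan)
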
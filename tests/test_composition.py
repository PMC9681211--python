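"""Condensation bookkeeping: monomer algebra, chain and glycan compositions,
atom census, and the sequence-vs-structure audit.

The chain-composition arithmetic is cross-checked against an independent
per-atom enumeration of CCD residue templates (a different code path and
data source from the monomer-formula table).
"""
import numpy as np
import pytest

from mabstitch.composition import (
    ChainSpec,
    ElementalComposition,
    audit_against_sequence,
    census,
    census_table,
    chain_composition,
    g0f,
    g1f,
    glycan_composition,
    monomer,
)
from mabstitch.errors import ChemistryError, TopologyError
from mabstitch.fixtures import make_ideal_peptide, perturb
from mabstitch.geometry import random_rigid_transform
from mabstitch.model import ONE_TO_THREE
from mabstitch.templates import polymer_atom_names, residue_template


def template_composition_oracle(sequence, protonation):
    """Independent oracle: count atoms of the in-polymer CCD templates."""
    counts = {el: 0 for el in "CHNOS"}
    for i, aa in enumerate(sequence):
        heavy, hyd = polymer_atom_names(
            ONE_TO_THREE[aa],
            nterm=(i == 0),
            cterm=(i == len(sequence) - 1),
            protonation=protonation,
        )
        t = residue_template(ONE_TO_THREE[aa])
        for name in heavy + hyd:
            counts[t.elements[name]] += 1
    return counts


def test_dipeptide_condensation():
    ec = chain_composition("GG", protonation="neutral")
    assert ec.as_dict() == {"C": 4, "H": 8, "N": 2, "O": 3, "S": 0}


def test_pyroglutamate_loses_ammonia():
    ec = chain_composition("Q", n_term="pyroglutamate", protonation="neutral")
    assert ec.as_dict() == {"C": 5, "H": 7, "N": 1, "O": 3, "S": 0}
    with pytest.raises(ChemistryError):
        chain_composition("AQ", n_term="pyroglutamate")


def test_free_glcnac_formula():
    t = g1f()
    assert monomer("NAG").as_dict() == {"C": 8, "H": 15, "N": 1, "O": 6, "S": 0}
    single = glycan_composition(_single_nag(), linked_to_protein=False)
    assert single.as_dict() == {"C": 8, "H": 15, "N": 1, "O": 6, "S": 0}


def _single_nag():
    from mabstitch.composition import GlycanTree

    t = GlycanTree()
    t.add_sugar("NAG1", "NAG")
    return t


def test_biantennary_glycan_pair_composition():
    """G1F (9 sugars) + G0F (8 sugars), both protein-linked: the combined
    formula of the two Fc glycans."""
    combined = glycan_composition(g1f()) + glycan_composition(g0f())
    assert combined["C"] == 118
    assert combined["H"] == 196
    assert combined["N"] == 8
    assert combined["O"] == 83
    assert combined.total == 405
    assert g1f().n_sugars == 9 and g0f().n_sugars == 8


def test_cyclic_glycan_rejected():
    t = g0f()
    t.add_linkage("NAGA", "NAG1", 3)  # closes a cycle back to the root
    with pytest.raises(TopologyError):
        glycan_composition(t)


def test_subtraction_cannot_go_negative():
    with pytest.raises(ChemistryError):
        monomer("G") - monomer("W")


@pytest.mark.parametrize("protonation", ["neutral", "charged"])
@pytest.mark.parametrize("seed", range(6))
def test_chain_composition_matches_template_atom_oracle(protonation, seed):
    rng = np.random.default_rng(200 + seed)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    seq = "".join(rng.choice(letters, size=rng.integers(1, 31)))
    ec = chain_composition(seq, protonation=protonation)
    assert ec.as_dict() == template_composition_oracle(seq, protonation)


def test_additivity_with_bookkept_losses():
    a, b = "GAVL", "WYTS"
    water = ElementalComposition.from_dict({"H": 2, "O": 1})
    whole = chain_composition(a + b, protonation="neutral")
    parts = chain_composition(a, protonation="neutral") + chain_composition(
        b, protonation="neutral"
    )
    assert whole == parts - water


def test_census_invariant_under_rigid_motion_and_reordering():
    s = make_ideal_peptide("WYAC", cterm_carboxyl=True)
    before = census(s)
    moved = random_rigid_transform(np.random.default_rng(3)).transform_structure(s)
    assert census(moved) == before
    shuffled = s.copy()
    shuffled.chains[0].residues[0].atoms.reverse()
    assert census(shuffled) == before


def test_census_empty_structure_is_all_zeros():
    from mabstitch.model import Structure

    assert census(Structure()).total == 0


def test_census_table_internal_consistency():
    light = chain_composition("GAVL", protonation="neutral")
    heavy = chain_composition("WYTSK", protonation="neutral")
    glyc = glycan_composition(g0f())
    table = census_table(light, heavy, glyc)
    for el in ("C", "N", "O", "S", "H"):
        row = table.loc[el]
        assert row["Total"] == 2 * row["L/M chain"] + 2 * row["H/V chain"] + row["H+V glycans"]
    assert (table.loc["Total"][:-1].sum() * 0 + table.loc["Total", "Total"]) == (
        2 * table.loc["Total", "L/M chain"]
        + 2 * table.loc["Total", "H/V chain"]
        + table.loc["Total", "H+V glycans"]
    )


class TestAudit:
    def _fixture(self):
        from mabstitch.assembly import add_hydrogens
        from mabstitch.model import Structure

        s = Structure(chains=[__import__("mabstitch.builder", fromlist=["build_peptide"]).build_peptide("GAVL", chain_id="A")])
        s = add_hydrogens(s)
        return s, {"A": ChainSpec("GAVL")}

    def test_self_consistent_fixture_gives_empty_report(self):
        s, specs = self._fixture()
        assert audit_against_sequence(s, specs).empty

    def test_single_missing_hydrogen_is_localized(self):
        s, specs = self._fixture()
        s.chains[0].residues[1].remove_atom("HB1")
        report = audit_against_sequence(s, specs)
        assert len(report) == 1
        row = report.iloc[0]
        assert (row["chain"], row["element"], row["difference"]) == ("A", "H", -1)

    def test_missing_glycan_discrepancy_equals_glycan_composition(self):
        from mabstitch.assembly import add_hydrogens
        from mabstitch.builder import build_peptide
        from mabstitch.model import Structure

        s = Structure(chains=[build_peptide("ANA", chain_id="A")])
        s = add_hydrogens(s)
        specs = {"A": ChainSpec("ANA", glycan=g0f())}
        report = audit_against_sequence(s, specs)
        expected = glycan_composition(g0f(), linked_to_protein=True)
        got = {r["element"]: -r["difference"] for _, r in report.iterrows()}
        # the chain keeps the amide H that glycosylation would remove, so the
        # hydrogen deficit is one less than the glycan's own H count
        assert got["C"] == expected["C"]
        assert got["O"] == expected["O"]
        assert got["N"] == expected["N"]
        assert got["H"] == expected["H"] - 1
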
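"""Covalent bond enumeration shared by the force field and ring analysis.

Bonds come from three sources: CCD template bonds filtered to the atoms
actually present in each residue, peptide bonds implied between consecutive
amino-acid residues of a chain, and the structure's explicit links
(disulfides, glycosidic and N-glycosidic bonds).
"""
from __future__ import annotations

import networkx as nx

from .model import AtomRef, Structure
from .templates import residue_template

#: reference lengths (Angstrom) for inter-residue bonds
INTER_BOND_LENGTH = {
    "peptide": 1.329,
    "disulfide": 2.05,
    "glycosidic": 1.43,
    "n_glycosidic": 1.45,
}


def covalent_bonds(
    s: Structure, include_hydrogens: bool = True
) -> list[tuple[AtomRef, AtomRef, str]]:
    """All covalent bonds as (ref_a, ref_b, kind) with kind one of
    'template', 'peptide', 'disulfide', 'glycosidic', 'n_glycosidic'."""
    bonds: list[tuple[AtomRef, AtomRef, str]] = []
    seen: set[frozenset] = set()

    def add(a: AtomRef, b: AtomRef, kind: str) -> None:
        key = frozenset((a, b))
        if key in seen:
            return
        seen.add(key)
        bonds.append((a, b, kind))

    for chain in s.chains:
        prev_amino = None
        for res in chain.residues:
            t = residue_template(res.name)
            present = set(res.atom_names())
            for a, b in t.bonds:
                if a in present and b in present:
                    if not include_hydrogens and (
                        t.elements[a] == "H" or t.elements[b] == "H"
                    ):
                        continue
                    add(
                        AtomRef(chain.id, res.seq_num, res.icode, a),
                        AtomRef(chain.id, res.seq_num, res.icode, b),
                        "template",
                    )
            if res.kind == "amino":
                if (
                    prev_amino is not None
                    and prev_amino.has_atom("C")
                    and res.has_atom("N")
                ):
                    add(
                        AtomRef(chain.id, prev_amino.seq_num, prev_amino.icode, "C"),
                        AtomRef(chain.id, res.seq_num, res.icode, "N"),
                        "peptide",
                    )
                prev_amino = res
    for link in s.links:
        if not include_hydrogens:
            pass  # explicit links never involve hydrogens
        kind = "peptide" if link.link_type == "explicit_peptide" else link.link_type
        add(link.atom_a, link.atom_b, kind)
    return bonds


def bond_graph(s: Structure, include_hydrogens: bool = True) -> nx.Graph:
    """Undirected simple graph with AtomRef nodes and covalent-bond edges."""
    g = nx.Graph()
    for ref, atom in s.iter_refs():
        if not include_hydrogens and atom.element == "H":
            continue
        g.add_node(ref, element=atom.element)
    for a, b, kind in covalent_bonds(s, include_hydrogens=include_hydrogens):
        if a in g and b in g:
            g.add_edge(a, b, kind=kind)
    return g
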
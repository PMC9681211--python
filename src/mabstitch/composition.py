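"""Elemental-composition bookkeeping for polypeptides and N-glycans.

A polymer's formula is the sum of its free monomers minus one water per
condensation bond, with three refinements that make per-chain accounting of a
glycosylated antibody well defined:

* pyroglutamate formation at a heavy-chain N-terminus loses NH3;
* each half-cystine engaged in a disulfide loses one hydrogen (charged to the
  chain that owns the cysteine);
* an N-glycosidic bond is split between its two sides: the Asn chain loses
  one amide hydrogen, the glycan loses the anomeric hydroxyl (OH).  Ordinary
  glycosidic bonds inside a glycan are charged entirely to the glycan (one
  water each).

Ionizable side chains follow the ``charged`` convention by default
(Lys/Arg +1 H, Asp/Glu -1 H, His neutral); termini are neutral (NH2/COOH).
A ``neutral`` convention (every group neutral) is available as a switch.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import ChemistryError, SelectionError, TopologyError
from .model import AMINO3, ONE_TO_THREE, SUGAR3, Structure

ELEMENTS = ("C", "N", "O", "S", "H")


@dataclass(frozen=True)
class ElementalComposition:
    """Non-negative integer atom counts per element, with element-wise algebra."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "ElementalComposition":
        for el, n in d.items():
            if el not in ELEMENTS:
                raise ChemistryError(f"unknown element {el!r}")
            if n < 0:
                raise ChemistryError(f"negative count for {el}")
        return cls(tuple((el, int(d.get(el, 0))) for el in ELEMENTS))

    @classmethod
    def zero(cls) -> "ElementalComposition":
        return cls.from_dict({})

    def as_dict(self) -> dict[str, int]:
        return {el: n for el, n in self.counts}

    def __getitem__(self, el: str) -> int:
        return self.as_dict()[el]

    @property
    def total(self) -> int:
        return sum(n for _, n in self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        a, b = self.as_dict(), other.as_dict()
        return ElementalComposition.from_dict({el: a[el] + b[el] for el in ELEMENTS})

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        a, b = self.as_dict(), other.as_dict()
        d = {el: a[el] - b[el] for el in ELEMENTS}
        if any(v < 0 for v in d.values()):
            raise ChemistryError(f"subtraction would go negative: {d}")
        return ElementalComposition.from_dict(d)

    def __mul__(self, k: int) -> "ElementalComposition":
        if k < 0:
            raise ChemistryError("negative multiplier")
        return ElementalComposition.from_dict({el: k * n for el, n in self.counts})

    __rmul__ = __mul__


def _ec(c=0, h=0, n=0, o=0, s=0) -> ElementalComposition:
    return ElementalComposition.from_dict({"C": c, "H": h, "N": n, "O": o, "S": s})


WATER = _ec(h=2, o=1)
AMMONIA = _ec(h=3, n=1)
HYDROGEN = _ec(h=1)
HYDROXYL = _ec(h=1, o=1)

#: Free neutral monomers: 20 amino acids, pyroglutamate, glycan sugars.
MONOMER_TABLE: dict[str, ElementalComposition] = {
    "GLY": _ec(2, 5, 1, 2), "ALA": _ec(3, 7, 1, 2), "SER": _ec(3, 7, 1, 3),
    "PRO": _ec(5, 9, 1, 2), "VAL": _ec(5, 11, 1, 2), "THR": _ec(4, 9, 1, 3),
    "CYS": _ec(3, 7, 1, 2, 1), "LEU": _ec(6, 13, 1, 2), "ILE": _ec(6, 13, 1, 2),
    "ASN": _ec(4, 8, 2, 3), "ASP": _ec(4, 7, 1, 4), "GLN": _ec(5, 10, 2, 3),
    "LYS": _ec(6, 14, 2, 2), "GLU": _ec(5, 9, 1, 4), "MET": _ec(5, 11, 1, 2, 1),
    "HIS": _ec(6, 9, 3, 2), "PHE": _ec(9, 11, 1, 2), "ARG": _ec(6, 14, 4, 2),
    "TYR": _ec(9, 11, 1, 3), "TRP": _ec(11, 12, 2, 2),
    "PCA": _ec(5, 7, 1, 3),  # pyroglutamate = Gln - NH3
    "NAG": _ec(8, 15, 1, 6),  # N-acetylglucosamine
    "BMA": _ec(6, 12, 0, 6), "MAN": _ec(6, 12, 0, 6), "GAL": _ec(6, 12, 0, 6),
    "FUC": _ec(6, 12, 0, 5),  # 6-deoxy sugar
}

#: Hydrogen adjustment per residue under the charged side-chain convention.
_CHARGED_H_ADJUST = {"LYS": +1, "ARG": +1, "ASP": -1, "GLU": -1}


def monomer(code: str) -> ElementalComposition:
    """Free-monomer composition by one-letter or three-letter code."""
    code3 = ONE_TO_THREE.get(code, code)
    try:
        return MONOMER_TABLE[code3]
    except KeyError:
        raise ChemistryError(f"unknown monomer code {code!r}") from None


def chain_composition(
    sequence: str,
    n_term: str = "free",
    n_disulfide_half_cystines: int = 0,
    n_glycosylation_sites: int = 0,
    protonation: str = "charged",
) -> ElementalComposition:
    """Elemental composition of one polypeptide chain.

    ``n_term='pyroglutamate'`` cyclizes the N-terminal Gln (requires the
    sequence to start with Q; loses NH3).  ``n_disulfide_half_cystines``
    counts the chain's cysteines engaged in any disulfide (one H lost each);
    ``n_glycosylation_sites`` counts N-glycosylated Asn (one amide H lost
    each, the glycan side is charged to the glycan).
    """
    if not sequence:
        raise ChemistryError("empty sequence")
    if n_term not in ("free", "pyroglutamate"):
        raise ChemistryError(f"unknown n_term {n_term!r}")
    if protonation not in ("charged", "neutral"):
        raise ChemistryError(f"unknown protonation convention {protonation!r}")
    if n_term == "pyroglutamate" and sequence[0] != "Q":
        raise ChemistryError("pyroglutamate requires an N-terminal Gln")
    if n_disulfide_half_cystines > sequence.count("C"):
        raise ChemistryError("more half-cystines than cysteines in sequence")

    total = ElementalComposition.zero()
    for letter in sequence:
        total = total + monomer(letter)
    total = total - (len(sequence) - 1) * WATER
    if n_term == "pyroglutamate":
        total = total - AMMONIA
    total = total - n_disulfide_half_cystines * HYDROGEN
    total = total - n_glycosylation_sites * HYDROGEN
    if protonation == "charged":
        net = sum(_CHARGED_H_ADJUST.get(ONE_TO_THREE.get(a, ""), 0) for a in sequence)
        if net > 0:
            total = total + net * HYDROGEN
        elif net < 0:
            total = total - (-net) * HYDROGEN
    return total


# ---------------------------------------------------------------------------
# Glycan trees
# ---------------------------------------------------------------------------

@dataclass
class GlycanTree:
    """Rooted tree of monosaccharides; edges carry the linkage position on the
    parent sugar (the child always links through its anomeric C1)."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    root: str | None = None

    def add_sugar(self, node_id: str, code: str) -> None:
        if code not in SUGAR3:
            raise ChemistryError(f"unknown sugar code {code!r}")
        self.graph.add_node(node_id, code=code)
        if self.root is None:
            self.root = node_id

    def add_linkage(self, parent: str, child: str, position: int) -> None:
        self.graph.add_edge(parent, child, position=position)

    def code_of(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["code"]

    @property
    def n_sugars(self) -> int:
        return self.graph.number_of_nodes()

    def validate(self) -> None:
        g = self.graph
        if self.root is None or g.number_of_nodes() == 0:
            raise TopologyError("empty glycan tree")
        if not nx.is_arborescence(g):
            raise TopologyError("glycan graph is not a rooted tree")
        roots = [n for n in g.nodes if g.in_degree(n) == 0]
        if roots != [self.root]:
            raise TopologyError("glycan tree root is inconsistent")


def biantennary_glycan(galactoses: int = 0, fucosylated: bool = True) -> GlycanTree:
    """Canonical biantennary N-glycan: Man3GlcNAc2 core, one GlcNAc per arm,
    optional core fucose and 0-2 terminal galactoses (G0F has none, G1F one)."""
    if galactoses not in (0, 1, 2):
        raise ChemistryError("0, 1 or 2 terminal galactoses")
    t = GlycanTree()
    t.add_sugar("NAG1", "NAG")           # reducing-end GlcNAc -> Asn
    t.add_sugar("NAG2", "NAG")
    t.add_linkage("NAG1", "NAG2", 4)
    if fucosylated:
        t.add_sugar("FUC", "FUC")
        t.add_linkage("NAG1", "FUC", 6)
    t.add_sugar("BMA", "BMA")
    t.add_linkage("NAG2", "BMA", 4)
    for arm, pos in (("A", 3), ("B", 6)):
        t.add_sugar(f"MAN{arm}", "MAN")
        t.add_linkage("BMA", f"MAN{arm}", pos)
        t.add_sugar(f"NAG{arm}", "NAG")
        t.add_linkage(f"MAN{arm}", f"NAG{arm}", 2)
    for i in range(galactoses):
        arm = "AB"[i]
        t.add_sugar(f"GAL{arm}", "GAL")
        t.add_linkage(f"NAG{arm}", f"GAL{arm}", 4)
    t.validate()
    return t


def g0f() -> GlycanTree:
    """The 8-sugar G0F glycan (no galactose), as on the V heavy chain."""
    return biantennary_glycan(galactoses=0)


def g1f() -> GlycanTree:
    """The 9-sugar G1F glycan (one terminal galactose), as on the H heavy chain."""
    return biantennary_glycan(galactoses=1)


def glycan_composition(tree: GlycanTree, linked_to_protein: bool = True) -> ElementalComposition:
    """Composition of a glycan: free sugars minus one water per glycosidic
    bond, minus OH at the root when N-linked to a protein Asn (whose amide H
    is charged to the protein chain, not the glycan)."""
    tree.validate()
    total = ElementalComposition.zero()
    for node in tree.graph.nodes:
        total = total + monomer(tree.code_of(node))
    total = total - tree.graph.number_of_edges() * WATER
    if linked_to_protein:
        total = total - HYDROXYL
    return total


# ---------------------------------------------------------------------------
# Atom census of a built structure
# ---------------------------------------------------------------------------

def census(s: Structure, group_by: str = "total"):
    """Exact per-element atom counts of a structure.

    ``group_by='total'`` returns one ElementalComposition; ``'chain'`` returns
    an ordered dict chain id -> ElementalComposition (chains sum to total).
    """
    if group_by not in ("chain", "total"):
        raise ChemistryError(f"unknown group_by {group_by!r}")
    per_chain: dict[str, ElementalComposition] = {}
    for c in s.chains:
        d = {el: 0 for el in ELEMENTS}
        for r in c.residues:
            for a in r.atoms:
                d[a.element] += 1
        per_chain[c.id] = ElementalComposition.from_dict(d)
    if group_by == "chain":
        return per_chain
    total = ElementalComposition.zero()
    for ec in per_chain.values():
        total = total + ec
    return total


def census_split(s: Structure) -> dict[str, dict[str, ElementalComposition]]:
    """Per chain, separate counts for amino-acid atoms and sugar atoms."""
    out: dict[str, dict[str, ElementalComposition]] = {}
    for c in s.chains:
        prot = {el: 0 for el in ELEMENTS}
        sug = {el: 0 for el in ELEMENTS}
        for r in c.residues:
            tgt = prot if r.kind == "amino" else sug
            for a in r.atoms:
                tgt[a.element] += 1
        out[c.id] = {
            "protein": ElementalComposition.from_dict(prot),
            "glycan": ElementalComposition.from_dict(sug),
        }
    return out


def census_table(
    light: ElementalComposition,
    heavy: ElementalComposition,
    glycans: ElementalComposition,
) -> pd.DataFrame:
    """Publication-layout census table: rows C,N,O,S,H + Total; columns are
    one light chain, one heavy chain (protein only), the combined H+V
    glycans, and the whole-molecule total (2 L + 2 H + glycans)."""
    rows = []
    for el in ELEMENTS:
        rows.append(
            {
                "Atom type": el,
                "L/M chain": light[el],
                "H/V chain": heavy[el],
                "H+V glycans": glycans[el],
                "Total": 2 * light[el] + 2 * heavy[el] + glycans[el],
            }
        )
    df = pd.DataFrame(rows).set_index("Atom type")
    df.loc["Total"] = df.sum(axis=0)
    return df


# ---------------------------------------------------------------------------
# Audit: built structure vs sequence-level prediction
# ---------------------------------------------------------------------------

@dataclass
class ChainSpec:
    """Sequence-level description of one chain for composition prediction."""

    sequence: str
    n_term: str = "free"
    n_disulfide_half_cystines: int = 0
    glycan: GlycanTree | None = None

    def predicted(self, protonation: str = "charged") -> ElementalComposition:
        ec = chain_composition(
            self.sequence,
            n_term=self.n_term,
            n_disulfide_half_cystines=self.n_disulfide_half_cystines,
            n_glycosylation_sites=0 if self.glycan is None else 1,
            protonation=protonation,
        )
        if self.glycan is not None:
            ec = ec + glycan_composition(self.glycan, linked_to_protein=True)
        return ec


def audit_against_sequence(
    s: Structure,
    chain_specs: dict[str, ChainSpec],
    protonation: str = "charged",
) -> pd.DataFrame:
    """Per-chain per-element difference (observed - predicted) between the
    structure's atom census and the sequence-level prediction.  An empty
    frame means the model is consistent with its sequences."""
    observed = census(s, group_by="chain")
    for cid in observed:
        if cid not in chain_specs:
            raise SelectionError(f"no ChainSpec for chain {cid!r}")
    rows = []
    for cid, spec in chain_specs.items():
        obs = observed.get(cid)
        if obs is None:
            raise SelectionError(f"chain {cid!r} not present in structure")
        pred = spec.predicted(protonation)
        for el in ELEMENTS:
            diff = obs[el] - pred[el]
            if diff != 0:
                rows.append(
                    {"chain": cid, "element": el, "observed": obs[el],
                     "predicted": pred[el], "difference": diff}
                )
    return pd.DataFrame(rows, columns=["chain", "element", "observed", "predicted", "difference"])
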
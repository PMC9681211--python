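"""Hierarchical coordinate model: Structure -> Chain -> Residue -> Atom.

The model is deliberately small and explicit: chains hold ordered residues,
residues hold ordered atoms, and all non-peptide covalent bonds (disulfides,
glycosidic and N-glycosidic links) are stored as explicit
:class:`CovalentLink` records on the structure.  Peptide connectivity is
implied between consecutive residues of the same chain and never stored.

Only the elements C, H, N, O and S occur in an IgG1 glycoprotein; anything
else is rejected up front so downstream bookkeeping can trust the alphabet.
"""
from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .errors import ChemistryError, SelectionError, TopologyError

ALLOWED_ELEMENTS = ("C", "H", "N", "O", "S")

#: Standard atomic weights (u), 4 decimals.
ATOMIC_MASS = {"C": 12.0110, "H": 1.0080, "N": 14.0070, "O": 15.9990, "S": 32.0600}

#: Three-letter codes treated as amino acids (20 standard + pyroglutamate).
AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "PCA",
}

#: Monosaccharide component codes used by the Fc N-glycans.
SUGAR3 = {"NAG", "BMA", "MAN", "GAL", "FUC"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "PCA": "Q",  # PCA is cyclized Gln
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "PCA"}


class AtomRef(NamedTuple):
    """Stable reference to an atom: (chain id, residue number, icode, atom name)."""

    chain_id: str
    seq_num: int
    icode: str
    atom_name: str


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        if self.element not in ALLOWED_ELEMENTS:
            raise ChemistryError(
                f"element {self.element!r} of atom {self.name!r} is outside the "
                f"supported alphabet {ALLOWED_ELEMENTS}"
            )
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ChemistryError(f"atom {self.name!r} has non-finite or non-3D coords")


@dataclass
class Residue:
    name: str
    seq_num: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def kind(self) -> str:
        """'amino' or 'sugar', derived from the residue name."""
        if self.name in AMINO3:
            return "amino"
        if self.name in SUGAR3:
            return "sugar"
        raise ChemistryError(f"unknown residue name {self.name!r}")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise SelectionError(f"residue {self.name} {self.seq_num}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def remove_atom(self, name: str) -> None:
        self.atoms = [a for a in self.atoms if a.name != name]


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seq_num: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.seq_num == seq_num and r.icode == icode:
                return r
        raise SelectionError(f"chain {self.id}: no residue {seq_num}{icode}")

    def has_residue(self, seq_num: int, icode: str = "") -> bool:
        return any(r.seq_num == seq_num and r.icode == icode for r in self.residues)

    def sequence(self) -> str:
        """One-letter sequence over amino-acid residues (PCA reads as Q)."""
        return "".join(
            THREE_TO_ONE[r.name] for r in self.residues if r.name in AMINO3
        )

    def amino_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.name in AMINO3]


@dataclass(frozen=True)
class CovalentLink:
    """Unordered covalent bond between two atoms of a Structure.

    link_type is one of 'disulfide', 'glycosidic', 'n_glycosidic',
    'explicit_peptide'.
    """

    atom_a: AtomRef
    atom_b: AtomRef
    link_type: str

    LINK_TYPES = ("disulfide", "glycosidic", "n_glycosidic", "explicit_peptide")

    def __post_init__(self) -> None:
        if self.link_type not in self.LINK_TYPES:
            raise TopologyError(f"unknown link type {self.link_type!r}")
        if self.link_type == "disulfide":
            if self.atom_a.atom_name != "SG" or self.atom_b.atom_name != "SG":
                raise TopologyError("disulfide endpoints must be SG atoms")

    def key(self) -> frozenset:
        return frozenset((self.atom_a, self.atom_b))

    def __eq__(self, other) -> bool:  # symmetric in endpoint order
        return (
            isinstance(other, CovalentLink)
            and self.key() == other.key()
            and self.link_type == other.link_type
        )

    def __hash__(self) -> int:
        return hash((self.key(), self.link_type))


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    links: list[CovalentLink] = field(default_factory=list)

    # -- lookup ---------------------------------------------------------
    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise SelectionError(f"no chain {chain_id!r}")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.id == chain_id for c in self.chains)

    def atom(self, ref: AtomRef) -> Atom:
        return self.chain(ref.chain_id).residue(ref.seq_num, ref.icode).atom(ref.atom_name)

    def has_atom(self, ref: AtomRef) -> bool:
        try:
            self.atom(ref)
            return True
        except SelectionError:
            return False

    # -- iteration ------------------------------------------------------
    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def iter_refs(self) -> Iterator[tuple[AtomRef, Atom]]:
        for c, r, a in self.iter_atoms():
            yield AtomRef(c.id, r.seq_num, r.icode, a.name), a

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def n_amino_acids(self) -> int:
        return sum(len(c.amino_residues()) for c in self.chains)

    # -- coordinates ----------------------------------------------------
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array in structure iteration order."""
        n = self.n_atoms()
        out = np.empty((n, 3))
        for i, (_, _, a) in enumerate(self.iter_atoms()):
            out[i] = a.coords
        return out

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms(), 3):
            raise ValueError("coordinate array shape mismatch")
        for i, (_, _, a) in enumerate(self.iter_atoms()):
            a.coords = xyz[i].copy()

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASS[a.element] for _, _, a in self.iter_atoms()])

    # -- links ----------------------------------------------------------
    def add_link(self, link: CovalentLink) -> None:
        for ref in (link.atom_a, link.atom_b):
            if not self.has_atom(ref):
                raise TopologyError(f"link references missing atom {ref}")
        if link in self.links:
            raise TopologyError(f"duplicate link {link}")
        self.links.append(link)

    def remove_link(self, link: CovalentLink) -> None:
        self.links = [l for l in self.links if l != link]

    def find_links(self, link_type: str | None = None) -> list[CovalentLink]:
        return [l for l in self.links if link_type is None or l.link_type == link_type]

    def validate(self) -> None:
        """Check structural invariants; raise TopologyError on violation."""
        for c in self.chains:
            if len(c.id) != 1:
                raise TopologyError(f"chain id {c.id!r} is not a single character")
            keys = [(r.seq_num, r.icode) for r in c.residues]
            if sorted(keys) != keys or len(set(keys)) != len(keys):
                raise TopologyError(f"chain {c.id}: residue numbering not increasing")
            for r in c.residues:
                names = r.atom_names()
                if len(set(names)) != len(names):
                    raise TopologyError(
                        f"chain {c.id} residue {r.seq_num}: duplicate atom names"
                    )
        seen = set()
        for l in self.links:
            for ref in (l.atom_a, l.atom_b):
                if not self.has_atom(ref):
                    raise TopologyError(f"link references missing atom {ref}")
            if l in seen:
                raise TopologyError(f"duplicate link {l}")
            seen.add(l)

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def renumber_serials(self) -> None:
        for i, (_, _, a) in enumerate(self.iter_atoms(), start=1):
            a.serial = i
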
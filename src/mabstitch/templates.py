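"""Ideal-geometry residue templates backed by the Chemical Component Dictionary.

Templates (atom names, elements, ideal coordinates, covalent bonds) for the 20
amino acids, pyroglutamate (PCA) and the glycan monosaccharides NAG, BMA, MAN,
GAL and FUC are taken from the CCD bundled with biotite, then specialized to
their in-polymer form:

* free-monomer leaving atoms (OXT/HXT carboxyl, the second amine hydrogen)
  are dropped except at the relevant terminus;
* ionizable side chains follow one of two protonation conventions --
  ``charged`` (Lys/Arg protonated, Asp/Glu deprotonated, His single ring NH)
  or ``neutral`` (every side chain in its neutral form);
* half-cystines lose HG, N-glycosylated Asn loses one amide hydrogen, and
  sugars lose their anomeric O1/HO1 (and the parent hydroxyl hydrogen) at
  each glycosidic bond.

The same tables drive side-chain rebuilding on mutation, hydrogen placement,
force-field topology and the elemental bookkeeping cross-checks.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import biotite.structure.info as _info

from .errors import ChemistryError, TopologyError
from .model import AMINO3, SUGAR3, ALLOWED_ELEMENTS

BACKBONE = ("N", "CA", "C", "O")

#: hydrogens removed per residue under each protonation convention
_PROTONATION_DROP = {
    "charged": {"ASP": ("HD2",), "GLU": ("HE2",), "HIS": ("HD1",)},
    "neutral": {"HIS": ("HD1",), "LYS": ("HZ3",), "ARG": ("HH12",)},
}

#: parent hydroxyl oxygen per glycosidic linkage position
LINKAGE_OXYGEN = {2: "O2", 3: "O3", 4: "O4", 6: "O6"}


@dataclass(frozen=True)
class ResidueTemplate:
    """Raw CCD component: every atom of the free monomer, with ideal coords."""

    name: str
    atom_names: tuple[str, ...]
    elements: dict[str, str]
    coords: dict[str, np.ndarray]
    bonds: tuple[tuple[str, str], ...]

    def neighbors(self, atom: str) -> list[str]:
        out = []
        for a, b in self.bonds:
            if a == atom:
                out.append(b)
            elif b == atom:
                out.append(a)
        return out

    def heavy_names(self) -> list[str]:
        return [n for n in self.atom_names if self.elements[n] != "H"]

    def hydrogens_on(self, heavy: str) -> list[str]:
        return [n for n in self.neighbors(heavy) if self.elements[n] == "H"]

    def parent_of_hydrogen(self, h: str) -> str:
        nb = self.neighbors(h)
        if len(nb) != 1:
            raise TopologyError(f"{self.name}: hydrogen {h} has {len(nb)} neighbors")
        return nb[0]


@lru_cache(maxsize=None)
def residue_template(name: str) -> ResidueTemplate:
    if name not in AMINO3 | SUGAR3:
        raise ChemistryError(f"no template for residue {name!r}")
    arr = _info.residue(name)
    names = tuple(str(n) for n in arr.atom_name)
    elements = {}
    coords = {}
    for i, n in enumerate(names):
        el = str(arr.element[i]).upper()
        if el not in ALLOWED_ELEMENTS:
            raise ChemistryError(f"template {name}: unsupported element {el}")
        elements[n] = el
        coords[n] = np.array(arr.coord[i], dtype=float)
    bond_dict = _info.bonds_in_residue(name)
    bonds = tuple(sorted((min(a, b), max(a, b)) for a, b in bond_dict))
    return ResidueTemplate(name, names, elements, coords, bonds)


def polymer_atom_names(
    name: str,
    *,
    nterm: bool = False,
    cterm: bool = False,
    protonation: str = "charged",
    disulfide: bool = False,
    glycosylated: bool = False,
) -> tuple[list[str], list[str]]:
    """(heavy atom names, hydrogen names) of a residue in its in-chain form.

    `nterm`/`cterm` keep the terminal amine hydrogens / carboxyl OXT+HXT
    (neutral NH2 / COOH forms).  `disulfide` drops HG of a half-cystine;
    `glycosylated` drops one amide hydrogen of an N-glycosylated Asn.
    """
    if protonation not in _PROTONATION_DROP:
        raise ChemistryError(f"unknown protonation convention {protonation!r}")
    t = residue_template(name)
    if name in SUGAR3:
        raise ChemistryError("use sugar_atom_names for monosaccharides")
    drop: set[str] = set()
    if not cterm:
        drop |= {"OXT", "HXT"}
    if name == "PCA":
        if not nterm:
            raise ChemistryError("PCA is only valid at an N-terminus")
    elif name == "PRO":
        # secondary amine: CCD carries a single N-H, present only at the N-terminus
        if not nterm:
            drop.add("H")
    else:
        if not nterm:
            drop.add("H2")
    drop |= set(_PROTONATION_DROP[protonation].get(name, ()))
    if disulfide:
        if name != "CYS":
            raise ChemistryError("disulfide flag only applies to CYS")
        drop.add("HG")
    if glycosylated:
        if name != "ASN":
            raise ChemistryError("glycosylated flag only applies to ASN")
        drop.add("HD22")
    heavy = [n for n in t.heavy_names() if n not in drop]
    hyd = [n for n in t.atom_names if t.elements[n] == "H" and n not in drop]
    return heavy, hyd


def sugar_atom_names(
    name: str,
    *,
    is_linked_child: bool,
    parent_linkage_positions: tuple[int, ...] = (),
) -> tuple[list[str], list[str]]:
    """In-glycan atom names of a monosaccharide.

    A sugar that is the child of a glycosidic (or N-glycosidic) bond loses its
    anomeric hydroxyl (O1 + HO1); for every outgoing linkage at position p it
    loses the hydroxyl hydrogen HO{p} (the oxygen becomes the bridge oxygen).
    """
    if name not in SUGAR3:
        raise ChemistryError(f"{name!r} is not a supported sugar")
    t = residue_template(name)
    drop: set[str] = set()
    if is_linked_child:
        drop |= {"O1", "HO1"}
    for p in parent_linkage_positions:
        if p not in LINKAGE_OXYGEN:
            raise ChemistryError(f"unsupported linkage position {p}")
        drop.add("HO" + str(p))
    heavy = [n for n in t.heavy_names() if n not in drop]
    hyd = [n for n in t.atom_names if t.elements[n] == "H" and n not in drop]
    return heavy, hyd


def template_bond_length(name: str, a: str, b: str) -> float:
    t = residue_template(name)
    return float(np.linalg.norm(t.coords[a] - t.coords[b]))


def template_angle(name: str, a: str, b: str, c: str) -> float:
    """Ideal a-b-c angle (radians) measured on the CCD template."""
    t = residue_template(name)
    v1 = t.coords[a] - t.coords[b]
    v2 = t.coords[c] - t.coords[b]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))
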
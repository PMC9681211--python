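"""Template-based hydrogen placement.

Hydrogens are placed per residue from the CCD ideal-geometry template: for
each hydrogen, a local frame of three bonded heavy atoms (the parent atom and
two of its covalent neighbours) is superposed from the template onto the
structure and the template hydrogen is carried along.  Because the frame is
local, side chains keep their hydrogens consistent with whatever rotamer they
are in.  Backbone amide hydrogens are the one cross-residue case and are
placed analytically, trans to the preceding carbonyl, on the bisector of the
C(prev)-N-CA opening.

Which hydrogens exist follows the composition module's conventions: a
hydrogen is added iff its parent heavy atom is present and it is not excluded
by the residue's context (terminus, protonation convention, half-cystine,
N-glycosylated Asn, glycosidic bridge oxygen).
"""
from __future__ import annotations

import numpy as np

from .errors import TopologyError
from .model import Atom, AtomRef, Residue, Structure
from .geometry import superpose
from .templates import residue_template, _PROTONATION_DROP


def _excluded_hydrogens(
    s: Structure,
    chain_id: str,
    res: Residue,
    *,
    nterm: bool,
    cterm: bool,
    protonation: str,
) -> set[str]:
    drop: set[str] = set(_PROTONATION_DROP[protonation].get(res.name, ()))
    if res.kind == "amino":
        if not cterm:
            drop.add("HXT")
        if res.name == "PRO":
            if not nterm:
                drop.add("H")
        elif res.name != "PCA":
            if not nterm:
                drop.add("H2")
    # context from explicit links
    for link in s.links:
        for me, other in ((link.atom_a, link.atom_b), (link.atom_b, link.atom_a)):
            if me.chain_id != chain_id or me.seq_num != res.seq_num or me.icode != res.icode:
                continue
            if link.link_type == "disulfide" and me.atom_name == "SG":
                drop.add("HG")
            elif link.link_type == "n_glycosidic" and me.atom_name == "ND2":
                drop.add("HD22")
            elif link.link_type in ("glycosidic", "n_glycosidic") and me.atom_name.startswith("O"):
                drop.add("HO" + me.atom_name[1:])
    return drop


def _place_by_frame(res: Residue, tname: str, h_name: str) -> np.ndarray:
    """Place hydrogen `h_name` by superposing a 3-heavy-atom template frame."""
    t = residue_template(tname)
    parent = t.parent_of_hydrogen(h_name)
    present = set(res.atom_names())
    frame = [parent]
    nb1 = [n for n in sorted(t.neighbors(parent)) if t.elements[n] != "H" and n in present]
    frame.extend(nb1[:2])
    if len(frame) < 3 and nb1:
        second = [
            n
            for n in sorted(t.neighbors(nb1[0]))
            if t.elements[n] != "H" and n != parent and n in present
        ]
        frame.extend(second[: 3 - len(frame)])
    if len(frame) < 3:
        raise TopologyError(
            f"{tname} {res.seq_num}: cannot build a frame to place {h_name} "
            f"(parent {parent}, present atoms {sorted(present)})"
        )
    tpl = np.array([t.coords[a] for a in frame])
    tgt = np.array([res.atom(a).coords for a in frame])
    tr, _ = superpose(tpl, tgt)
    return tr.apply(t.coords[h_name][None, :])[0]


def _place_amide_h(res: Residue, prev_c: np.ndarray) -> np.ndarray:
    t = residue_template(res.name)
    nh = float(np.linalg.norm(t.coords["H"] - t.coords["N"]))
    n = res.atom("N").coords
    ca = res.atom("CA").coords
    u = (ca - n) / np.linalg.norm(ca - n)
    v = (prev_c - n) / np.linalg.norm(prev_c - n)
    d = -(u + v)
    d /= np.linalg.norm(d)
    return n + nh * d


def place_residue_hydrogens(
    s: Structure,
    chain_id: str,
    res: Residue,
    *,
    nterm: bool,
    cterm: bool,
    prev_c: np.ndarray | None,
    protonation: str = "charged",
) -> None:
    """Strip and re-place all hydrogens of one residue in place."""
    res.atoms = [a for a in res.atoms if a.element != "H"]
    t = residue_template(res.name)
    drop = _excluded_hydrogens(
        s, chain_id, res, nterm=nterm, cterm=cterm, protonation=protonation
    )
    present = set(res.atom_names())
    for h in t.atom_names:
        if t.elements[h] != "H" or h in drop:
            continue
        parent = t.parent_of_hydrogen(h)
        if parent not in present:
            continue  # heavy atom condensed away (OXT, O1, bridge oxygens...)
        if h == "H" and parent == "N" and res.kind == "amino" and not nterm:
            if prev_c is None:
                raise TopologyError(
                    f"residue {res.seq_num}: amide H needs the preceding carbonyl"
                )
            xyz = _place_amide_h(res, prev_c)
        else:
            xyz = _place_by_frame(res, res.name, h)
        res.atoms.append(Atom(serial=0, name=h, element="H", coords=xyz))


def add_hydrogens(s: Structure, protonation: str = "charged") -> Structure:
    """Return a copy of the structure with all hydrogens (re)placed."""
    out = s.copy()
    for chain in out.chains:
        aminos = chain.amino_residues()
        first = aminos[0] if aminos else None
        last = aminos[-1] if aminos else None
        prev_c: np.ndarray | None = None
        for res in chain.residues:
            if res.kind == "amino":
                place_residue_hydrogens(
                    out,
                    chain.id,
                    res,
                    nterm=res is first,
                    cterm=res is last,
                    prev_c=prev_c,
                    protonation=protonation,
                )
                prev_c = res.atom("C").coords if res.has_atom("C") else None
            else:
                place_residue_hydrogens(
                    out, chain.id, res, nterm=False, cterm=False, prev_c=None,
                    protonation=protonation,
                )
    out.renumber_serials()
    return out
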
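"""Reading and writing coordinate files and sequences.

PDB and PDBx/mmCIF parsing/writing is delegated to gemmi; this module maps
between gemmi's hierarchy and the package's :class:`~mabstitch.model.Structure`,
resolving alternate locations to the highest-occupancy conformer (ties broken
toward altloc 'A') and translating SSBOND/LINK records to explicit
:class:`~mabstitch.model.CovalentLink` entries and back.  Output is PDB:
ATOM for amino acids, HETATM for sugars, SSBOND for disulfides, LINK for
(N-)glycosidic bonds, TER between chains, coordinates at 3 decimals.
"""
from __future__ import annotations

import gemmi
from Bio import SeqIO

from .errors import CapacityError, ChemistryError, FormatError
from .model import (
    AMINO3,
    ALLOWED_ELEMENTS,
    Atom,
    AtomRef,
    Chain,
    CovalentLink,
    Residue,
    Structure,
)

_VALID_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


def _link_type_from_atoms(a: AtomRef, b: AtomRef) -> str:
    names = {a.atom_name, b.atom_name}
    if names == {"SG"}:
        return "disulfide"
    if "ND2" in names:
        return "n_glycosidic"
    if "C1" in names:
        return "glycosidic"
    return "explicit_peptide"


def read_structure(path: str, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a Structure.

    The format is inferred from the extension unless given explicitly as
    'pdb' or 'mmcif'.  Alternate locations are collapsed to the
    highest-occupancy conformer; SSBOND/LINK records become covalent links.
    """
    try:
        if format is None:
            st = gemmi.read_structure(str(path))
        elif format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            raise FormatError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        return Structure()
    model = st[0]
    out = Structure()
    serial = 0
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            res = Residue(
                name=gres.name,
                seq_num=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
            )
            # collapse altlocs: highest occupancy wins, ties to smallest altloc
            by_name: dict[str, gemmi.Atom] = {}
            for ga in gres:
                cur = by_name.get(ga.name)
                if (
                    cur is None
                    or ga.occ > cur.occ
                    or (ga.occ == cur.occ and (ga.altloc or "~") < (cur.altloc or "~"))
                ):
                    by_name[ga.name] = ga
            for ga in gres:
                if by_name.get(ga.name) is not ga:
                    continue
                el = ga.element.name.upper()
                if el not in ALLOWED_ELEMENTS:
                    raise ChemistryError(
                        f"{path}: atom {gchain.name}/{gres.seqid.num}/{ga.name} has "
                        f"unsupported element {el!r}"
                    )
                serial += 1
                res.atoms.append(
                    Atom(
                        serial=serial,
                        name=ga.name,
                        element=el,
                        coords=[ga.pos.x, ga.pos.y, ga.pos.z],
                        occupancy=ga.occ,
                        b_factor=ga.b_iso,
                    )
                )
            chain.residues.append(res)
        out.chains.append(chain)
    for con in st.connections:
        refs = []
        for partner in (con.partner1, con.partner2):
            refs.append(
                AtomRef(
                    partner.chain_name,
                    partner.res_id.seqid.num,
                    (partner.res_id.seqid.icode or "").strip(),
                    partner.atom_name,
                )
            )
        a, b = refs
        if not (out.has_atom(a) and out.has_atom(b)):
            continue  # e.g. link to a stripped conformer or absent chain
        if con.type == gemmi.ConnectionType.Disulf:
            ltype = "disulfide"
        else:
            ltype = _link_type_from_atoms(a, b)
        link = CovalentLink(a, b, ltype)
        if link not in out.links:
            out.links.append(link)
    return out


def write_structure(s: Structure, path: str) -> None:
    """Write a Structure as a PDB file (see module docstring for records)."""
    if s.n_atoms() > 99999:
        raise CapacityError(
            f"{s.n_atoms()} atoms exceed the PDB serial limit; write mmCIF instead"
        )
    s.validate()
    st = gemmi.Structure()
    st.name = "mabstitch"
    model = gemmi.Model("1")
    serial = 0
    for chain in s.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
            gres.het_flag = "A" if res.kind == "amino" else "H"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                serial += 1
                ga.serial = serial
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    for link in s.links:
        con = gemmi.Connection()
        con.name = link.link_type
        con.type = (
            gemmi.ConnectionType.Disulf
            if link.link_type == "disulfide"
            else gemmi.ConnectionType.Covale
        )
        for attr, ref in (("partner1", link.atom_a), ("partner2", link.atom_b)):
            res = s.chain(ref.chain_id).residue(ref.seq_num, ref.icode)
            addr = gemmi.AtomAddress(
                ref.chain_id,
                gemmi.SeqId(ref.seq_num, ref.icode or " "),
                res.name,
                ref.atom_name,
            )
            setattr(con, attr, addr)
        st.connections.append(con)
    doc_ok = st.write_pdb(str(path))
    return doc_ok


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Read FASTA entries as (id, uppercase sequence) pairs.

    Raises FormatError on an empty file or on sequences containing letters
    outside the 20 amino-acid alphabet.
    """
    entries: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        bad = set(seq) - _VALID_AA_LETTERS
        if bad:
            raise FormatError(f"{path}: sequence {rec.id!r} has non-amino letters {sorted(bad)}")
        entries.append((rec.id, seq))
    if not entries:
        raise FormatError(f"{path}: no FASTA entries")
    return entries
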
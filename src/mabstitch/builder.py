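"""Ideal-geometry construction primitives.

Peptide backbones are grown atom by atom with the natural-extension reference
frame (NeRF) recurrence from bond length / bond angle / torsion triples.
Per-residue internal geometry (including the N-CA-C angle used for backbone
placement) is measured from the CCD template of that residue type, so copying
a template rigidly onto its three backbone atoms is exact and every
intra-residue bond and angle of a freshly built chain equals its template
value to machine precision.  Inter-residue geometry uses the standard peptide
constants below.

Glycans are grown sugar by sugar along their tree, each child oriented so its
anomeric carbon takes the place marked by the parent's linkage oxygen.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .composition import GlycanTree
from .errors import ChemistryError, GeometryError
from .geometry import RigidTransform, superpose
from .model import Atom, AtomRef, Chain, CovalentLink, Residue, Structure, ONE_TO_THREE
from .templates import LINKAGE_OXYGEN, polymer_atom_names, residue_template, sugar_atom_names

# inter-residue peptide constants (lengths in Angstrom, angles in degrees)
PEPTIDE_C_N = 1.329
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

CONFORMATIONS = {
    "extended": {"phi": 180.0, "psi": 180.0},
    "helical": {"phi": -57.0, "psi": -47.0},
}

GLYCOSIDIC_C1_O = 1.43
N_GLYCOSIDIC_C1_ND2 = 1.45


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position of atom d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise GeometryError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _three_letter(letter: str) -> str:
    try:
        return ONE_TO_THREE[letter]
    except KeyError:
        raise ChemistryError(f"unknown amino-acid letter {letter!r}") from None


def _backbone_geom(name: str) -> tuple[float, float, float]:
    """(N-CA, CA-C, angle N-CA-C deg) measured from the residue template."""
    t = residue_template(name)
    n, ca, c = t.coords["N"], t.coords["CA"], t.coords["C"]
    v1, v2 = n - ca, c - ca
    ang = np.degrees(
        np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    )
    return float(np.linalg.norm(v1)), float(np.linalg.norm(v2)), float(ang)


def build_residue_on_backbone(
    name: str,
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    atom_names: list[str],
    seq_num: int,
    skip: tuple[str, ...] = ("N", "CA", "C"),
) -> Residue:
    """Residue with the given atoms: N/CA/C at the supplied positions, every
    other atom copied from the rigidly superposed CCD template."""
    t = residue_template(name)
    tpl = np.array([t.coords["N"], t.coords["CA"], t.coords["C"]])
    tr, _ = superpose(tpl, np.array([n, ca, c]))
    res = Residue(name=name, seq_num=seq_num)
    placed = {"N": n, "CA": ca, "C": c}
    for an in atom_names:
        if an in skip and an in placed:
            xyz = placed[an]
        elif an in placed:
            xyz = placed[an]
        else:
            xyz = tr.apply(t.coords[an][None, :])[0]
        res.atoms.append(Atom(serial=0, name=an, element=t.elements[an], coords=xyz))
    return res


def build_peptide(
    sequence: str,
    conformation: str = "extended",
    chain_id: str = "A",
    start_num: int = 1,
    pca_nterm: bool = False,
    cterm_carboxyl: bool = True,
    protonation: str = "charged",
) -> Chain:
    """Ideal-geometry heavy-atom peptide chain (hydrogens added separately).

    The first residue sits in a canonical pose (N at the origin, CA on +x,
    C in the xy plane), so the construction is fully deterministic.
    """
    if conformation not in CONFORMATIONS:
        raise ChemistryError(f"unknown conformation {conformation!r}")
    if not sequence:
        raise ChemistryError("empty sequence")
    if pca_nterm and sequence[0] != "Q":
        raise ChemistryError("pyroglutamate requires an N-terminal Gln")
    phi = CONFORMATIONS[conformation]["phi"]
    psi = CONFORMATIONS[conformation]["psi"]

    names3 = [_three_letter(a) for a in sequence]
    if pca_nterm:
        names3[0] = "PCA"

    chain = Chain(id=chain_id)
    prev_n = prev_ca = prev_c = None
    backbones: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for i, name in enumerate(names3):
        d_nca, d_cac, ang_ncac = _backbone_geom(name)
        if i == 0:
            n = np.zeros(3)
            ca = np.array([d_nca, 0.0, 0.0])
            ang = np.deg2rad(ang_ncac)
            c = ca + d_cac * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            n = place_atom(prev_n, prev_ca, prev_c, PEPTIDE_C_N, ANGLE_CA_C_N, psi)
            ca = place_atom(prev_ca, prev_c, n, d_nca, ANGLE_C_N_CA, OMEGA)
            c = place_atom(prev_c, n, ca, d_cac, ang_ncac, phi)
        backbones.append((n, ca, c))
        prev_n, prev_ca, prev_c = n, ca, c

    for i, name in enumerate(names3):
        nterm = i == 0
        cterm = i == len(names3) - 1
        heavy, _ = polymer_atom_names(
            name,
            nterm=nterm,
            cterm=cterm and cterm_carboxyl,
            protonation=protonation,
        )
        n, ca, c = backbones[i]
        res = build_residue_on_backbone(name, n, ca, c, heavy, start_num + i)
        # carbonyl O (and OXT) follow psi so the peptide plane is exact
        t = residue_template(name)
        ang_cacO = np.degrees(
            _angle(t.coords["CA"], t.coords["C"], t.coords["O"])
        )
        d_cO = float(np.linalg.norm(t.coords["O"] - t.coords["C"]))
        o = place_atom(n, ca, c, d_cO, ang_cacO, psi + 180.0)
        res.atom("O").coords = o
        if cterm and cterm_carboxyl and res.has_atom("OXT"):
            ang_cacOXT = np.degrees(_angle(t.coords["CA"], t.coords["C"], t.coords["OXT"]))
            d_cOXT = float(np.linalg.norm(t.coords["OXT"] - t.coords["C"]))
            oxt = place_atom(n, ca, c, d_cOXT, ang_cacOXT, psi)
            res.atom("OXT").coords = oxt
        chain.residues.append(res)
    return chain


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    return float(
        np.arccos(
            np.clip(
                np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1
            )
        )
    )


# ---------------------------------------------------------------------------
# Glycan construction
# ---------------------------------------------------------------------------

def _orient_child_sugar(
    code: str, incoming_dir: np.ndarray, c1_target: np.ndarray
) -> RigidTransform:
    """Transform placing a sugar template so C1 sits at `c1_target` with its
    (removed) anomeric O1 pointing back along `incoming_dir`."""
    t = residue_template(code)
    v_tpl = t.coords["O1"] - t.coords["C1"]
    v_tpl /= np.linalg.norm(v_tpl)
    v_tgt = -incoming_dir / np.linalg.norm(incoming_dir)
    rot, _ = Rotation.align_vectors(v_tgt[None, :], v_tpl[None, :])
    R = rot.as_matrix()
    trans = c1_target - R @ t.coords["C1"]
    return RigidTransform(R, trans)


def attach_glycan(
    s: Structure,
    chain_id: str,
    asn_seq_num: int,
    tree: GlycanTree,
    first_seq_num: int = 601,
) -> Structure:
    """Attach a glycan tree to Asn `asn_seq_num` of a chain.

    Sugar residues are appended to the same chain, numbered consecutively
    from `first_seq_num` in a deterministic depth-first order.  The Asn loses
    one amide hydrogen if hydrogens are present; links (one N-glycosidic at
    the root, one glycosidic per tree edge) are recorded.
    """
    tree.validate()
    out = s.copy()
    chain = out.chain(chain_id)
    asn = chain.residue(asn_seq_num)
    if asn.name != "ASN":
        raise ChemistryError(f"residue {asn_seq_num} of chain {chain_id} is not ASN")
    nd2 = asn.atom("ND2").coords
    cg = asn.atom("CG").coords
    if asn.has_atom("HD22"):
        asn.remove_atom("HD22")

    seq_num = first_seq_num
    node_res: dict[str, Residue] = {}
    order = _dfs_order(tree)
    out_positions = {
        n: sorted(tree.graph.edges[n, ch]["position"] for ch in tree.graph.successors(n))
        for n in tree.graph.nodes
    }
    for node in order:
        code = tree.code_of(node)
        if node == tree.root:
            anchor, anchor_nb, bond = nd2, cg, N_GLYCOSIDIC_C1_ND2
        else:
            parent = next(tree.graph.predecessors(node))
            pos = tree.graph.edges[parent, node]["position"]
            pres = node_res[parent]
            o_name = LINKAGE_OXYGEN[pos]
            anchor = pres.atom(o_name).coords
            pc = residue_template(tree.code_of(parent))
            carbon = next(
                n for n in pc.neighbors(o_name) if pc.elements[n] == "C"
            )
            anchor_nb = pres.atom(carbon).coords
            bond = GLYCOSIDIC_C1_O
        d = anchor - anchor_nb
        d /= np.linalg.norm(d)
        c1_target = anchor + bond * d
        tr = _orient_child_sugar(code, -d, c1_target)
        heavy, hyd = sugar_atom_names(
            code,
            is_linked_child=True,
            parent_linkage_positions=tuple(out_positions[node]),
        )
        t = residue_template(code)
        res = Residue(name=code, seq_num=seq_num)
        has_h = any(a.element == "H" for a in asn.atoms)
        for an in heavy + (hyd if has_h else []):
            res.atoms.append(
                Atom(
                    serial=0,
                    name=an,
                    element=t.elements[an],
                    coords=tr.apply(t.coords[an][None, :])[0],
                )
            )
        chain.residues.append(res)
        node_res[node] = res
        seq_num += 1

    # record links
    root_res = node_res[tree.root]
    out.add_link(
        CovalentLink(
            AtomRef(chain_id, asn_seq_num, "", "ND2"),
            AtomRef(chain_id, root_res.seq_num, "", "C1"),
            "n_glycosidic",
        )
    )
    for parent, child in tree.graph.edges:
        pos = tree.graph.edges[parent, child]["position"]
        out.add_link(
            CovalentLink(
                AtomRef(chain_id, node_res[parent].seq_num, "", LINKAGE_OXYGEN[pos]),
                AtomRef(chain_id, node_res[child].seq_num, "", "C1"),
                "glycosidic",
            )
        )
    return out


def _dfs_order(tree: GlycanTree) -> list[str]:
    order: list[str] = []

    def visit(node: str) -> None:
        order.append(node)
        for child in sorted(tree.graph.successors(node)):
            visit(child)

    visit(tree.root)
    return order
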
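"""The model-construction procedure: hinge editing, splicing, mutation,
terminus completion, disulfide bookkeeping and the five-part graft.

The whole-antibody model is grafted from five parts -- two Fabs, one Fc, an
upper hinge carrying the disulfide core, and a lower hinge -- by rigid
superposition on shared junction residues.  The hinge donor supplies the
hinge conformation; donor surplus residues are removed and the gap closed by
moving the downstream fragment onto the recorded backbone frame of the
deleted anchor residue, after which mutations bring the hinge to the target
sequence and staged minimization relieves the residual junction strain.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .builder import build_peptide, build_residue_on_backbone
from .errors import (
    AssemblyError,
    ChemistryError,
    GeometryError,
    ScriptError,
    SpliceError,
)
from .geometry import RigidTransform, superpose
from .hydrogens import add_hydrogens, place_residue_hydrogens  # re-exported
from .model import (
    AMINO3,
    AtomRef,
    Chain,
    CovalentLink,
    ONE_TO_THREE,
    Residue,
    Structure,
)
from .templates import polymer_atom_names, residue_template

__all__ = [
    "EditOp",
    "EditScript",
    "SpliceSpec",
    "AssemblyPart",
    "Junction",
    "AssemblyPlan",
    "apply_edit_script",
    "splice",
    "mutate_residue",
    "extend_terminus",
    "set_disulfide",
    "add_hydrogens",
    "assemble",
]

BACKBONE_FRAME = ("N", "CA", "C")


# ---------------------------------------------------------------------------
# Edit scripts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EditOp:
    """A single edit: kind 'delete' removes residues first..last (inclusive);
    kind 'substitute' mutates residue `first` to amino acid `new_aa`."""

    kind: str
    first: int
    last: int | None = None
    new_aa: str | None = None

    def __post_init__(self):
        if self.kind not in ("delete", "substitute"):
            raise ScriptError(f"unknown edit kind {self.kind!r}")
        if self.kind == "substitute" and (self.new_aa is None or self.new_aa not in ONE_TO_THREE):
            raise ScriptError(f"substitution needs a standard amino acid, got {self.new_aa!r}")


@dataclass
class EditScript:
    chain_id: str
    ops: list[EditOp] = field(default_factory=list)


def apply_edit_script(s: Structure, script: EditScript) -> Structure:
    """Apply deletions and substitutions, in order, to one chain."""
    out = s.copy()
    for op in script.ops:
        chain = out.chain(script.chain_id)
        if op.kind == "delete":
            last = op.last if op.last is not None else op.first
            targets = [r for r in chain.residues if op.first <= r.seq_num <= last]
            if not targets:
                raise ScriptError(
                    f"delete {op.first}-{last}: no such residues in chain {script.chain_id}"
                )
            keep = {(r.seq_num, r.icode) for r in targets}
            chain.residues = [r for r in chain.residues if (r.seq_num, r.icode) not in keep]
            out.links = [
                l
                for l in out.links
                if not any(
                    ref.chain_id == script.chain_id and (ref.seq_num, ref.icode) in keep
                    for ref in (l.atom_a, l.atom_b)
                )
            ]
        else:
            if not chain.has_residue(op.first):
                raise ScriptError(
                    f"substitute {op.first}: no such residue in chain {script.chain_id}"
                )
            out = mutate_residue(out, script.chain_id, op.first, op.new_aa)
    return out


# ---------------------------------------------------------------------------
# Splice
# ---------------------------------------------------------------------------

@dataclass
class SpliceSpec:
    """Close the gap left by removing donor hinge surplus: residues from
    `anchor` up to (but excluding) `downstream_first` are removed, the
    anchor's backbone frame is recorded first, and the entire downstream
    fragment is rigidly moved so its first residue's backbone lands on that
    frame.  `chain_ids` lists every chain spliced (both heavy chains)."""

    chain_ids: list[str]
    anchor: int
    downstream_first: int
    renumber: bool = True

    def __post_init__(self):
        if self.anchor >= self.downstream_first:
            raise SpliceError("anchor must precede the first retained downstream residue")


def splice(s: Structure, spec: SpliceSpec) -> Structure:
    out = s.copy()
    for cid in spec.chain_ids:
        chain = out.chain(cid)
        try:
            anchor_res = chain.residue(spec.anchor)
            anchor_frame = np.array([anchor_res.atom(a).coords for a in BACKBONE_FRAME])
        except Exception as exc:
            raise SpliceError(f"chain {cid}: anchor {spec.anchor} unusable: {exc}") from exc
        down = [r for r in chain.residues if r.seq_num >= spec.downstream_first]
        if not down:
            raise SpliceError(f"chain {cid}: no residues at/after {spec.downstream_first}")
        first = down[0]
        try:
            mobile = np.array([first.atom(a).coords for a in BACKBONE_FRAME])
        except Exception as exc:
            raise SpliceError(
                f"chain {cid}: residue {first.seq_num} lacks backbone atoms: {exc}"
            ) from exc
        tr, _ = superpose(mobile, anchor_frame)
        # drop anchor..downstream-1
        removed = {
            (r.seq_num, r.icode)
            for r in chain.residues
            if spec.anchor <= r.seq_num < spec.downstream_first
        }
        chain.residues = [r for r in chain.residues if (r.seq_num, r.icode) not in removed]
        out.links = [
            l
            for l in out.links
            if not any(
                ref.chain_id == cid and (ref.seq_num, ref.icode) in removed
                for ref in (l.atom_a, l.atom_b)
            )
        ]
        shift = spec.downstream_first - spec.anchor
        remap = {}
        for r in chain.residues:
            if r.seq_num >= spec.downstream_first:
                for a in r.atoms:
                    a.coords = tr.apply(a.coords[None, :])[0]
                if spec.renumber:
                    remap[(r.seq_num, r.icode)] = r.seq_num - shift
                    r.seq_num -= shift
        if remap:
            out.links = [
                CovalentLink(
                    _remap_ref(l.atom_a, cid, remap),
                    _remap_ref(l.atom_b, cid, remap),
                    l.link_type,
                )
                for l in out.links
            ]
    return out


def _remap_ref(ref: AtomRef, chain_id: str, remap: dict) -> AtomRef:
    if ref.chain_id == chain_id and (ref.seq_num, ref.icode) in remap:
        return AtomRef(ref.chain_id, remap[(ref.seq_num, ref.icode)], ref.icode, ref.atom_name)
    return ref


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

_CLASH_CUTOFF = 2.0  # Angstrom, heavy-heavy
_CHI1_OFFSETS = (0.0, 120.0, -120.0, 180.0, 60.0, -60.0)


def mutate_residue(s: Structure, chain_id: str, seq_num: int, target_aa: str) -> Structure:
    """Replace a residue's side chain with `target_aa` built from ideal
    template geometry, keeping N/CA/C/O (and CB when shared).

    The template's own conformation serves as the single deterministic
    rotamer; if any rebuilt side-chain heavy atom comes within 2.0 A of a
    non-bonded heavy atom, a small set of chi1 rotations is tried and the
    least-clashing kept.
    """
    if target_aa not in ONE_TO_THREE:
        raise ChemistryError(f"unknown target amino acid {target_aa!r}")
    new_name = ONE_TO_THREE[target_aa]
    out = s.copy()
    chain = out.chain(chain_id)
    res = chain.residue(seq_num)
    if res.kind != "amino":
        raise ChemistryError(f"residue {seq_num} of chain {chain_id} is not an amino acid")
    had_h = any(a.element == "H" for a in res.atoms)
    n, ca, c = (res.atom(a).coords for a in BACKBONE_FRAME)
    keep_cb = res.has_atom("CB") and new_name != "GLY"
    old_cb = res.atom("CB").coords if keep_cb else None
    o_coords = res.atom("O").coords if res.has_atom("O") else None
    oxt = res.atom("OXT").coords if res.has_atom("OXT") else None

    aminos = chain.amino_residues()
    nterm = res is aminos[0]
    cterm = res is aminos[-1]
    heavy, _ = polymer_atom_names(new_name, nterm=nterm, cterm=cterm and oxt is not None)
    new_res = build_residue_on_backbone(new_name, n, ca, c, heavy, seq_num)
    new_res.icode = res.icode
    if o_coords is not None and new_res.has_atom("O"):
        new_res.atom("O").coords = o_coords
    if oxt is not None and new_res.has_atom("OXT"):
        new_res.atom("OXT").coords = oxt
    if old_cb is not None and new_res.has_atom("CB"):
        # preserve the existing CB and hang the ideal side chain off it
        t = residue_template(new_name)
        tpl = np.array([t.coords["N"], t.coords["CA"], t.coords["CB"]])
        tr, _ = superpose(tpl, np.array([n, ca, old_cb]))
        side = _side_chain_names(new_name)
        for a in new_res.atoms:
            if a.name in side:
                a.coords = tr.apply(t.coords[a.name][None, :])[0]
        new_res.atom("CB").coords = old_cb

    idx = chain.residues.index(res)
    chain.residues[idx] = new_res

    side = [a for a in new_res.atoms if a.name in _side_chain_names(new_name)]
    if side:
        best = None
        for k, off in enumerate(_CHI1_OFFSETS):
            coords = _rotate_chi1(new_res, off)
            n_clash = _count_clashes(out, chain_id, new_res, coords)
            if best is None or n_clash < best[0]:
                best = (n_clash, k, coords)
            if n_clash == 0 and k == 0:
                break
        for a, xyz in zip(
            [a for a in new_res.atoms if a.name in _side_chain_names(new_name)], best[2]
        ):
            a.coords = xyz

    if had_h:
        prev_c = None
        if idx > 0 and chain.residues[idx - 1].has_atom("C"):
            prev_c = chain.residues[idx - 1].atom("C").coords
        place_residue_hydrogens(
            out, chain_id, new_res, nterm=nterm, cterm=cterm, prev_c=prev_c
        )
    return out


def _side_chain_names(name: str) -> set[str]:
    t = residue_template(name)
    backbone = {"N", "CA", "C", "O", "OXT", "CB"}
    return {a for a in t.heavy_names() if a not in backbone}


def _rotate_chi1(res: Residue, offset_deg: float) -> list[np.ndarray]:
    side = _side_chain_names(res.name)
    coords = [res.atom(a.name).coords.copy() for a in res.atoms if a.name in side]
    if abs(offset_deg) < 1e-12 or not res.has_atom("CB"):
        return coords
    ca = res.atom("CA").coords
    cb = res.atom("CB").coords
    axis = cb - ca
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(offset_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    return [R @ (xyz - cb) + cb for xyz in coords]


def _count_clashes(
    s: Structure, chain_id: str, res: Residue, side_coords: list[np.ndarray]
) -> int:
    if not side_coords:
        return 0
    others = []
    for c, r, a in s.iter_atoms():
        if a.element == "H":
            continue
        if c.id == chain_id and r.seq_num == res.seq_num and r.icode == res.icode:
            continue
        others.append(a.coords)
    if not others:
        return 0
    others = np.array(others)
    n = 0
    for xyz in side_coords:
        d2 = np.einsum("ij,ij->i", others - xyz, others - xyz)
        n += int(np.sum(d2 < _CLASH_CUTOFF**2))
    return n


# ---------------------------------------------------------------------------
# Terminus extension
# ---------------------------------------------------------------------------

def extend_terminus(s: Structure, chain_id: str, residues: str, end: str = "C") -> Structure:
    """Append `residues` at a chain terminus with ideal extended geometry,
    continuing the chain's numbering.  Empty extension is a no-op."""
    if end not in ("N", "C"):
        raise ChemistryError("end must be 'N' or 'C'")
    if residues == "":
        return s.copy()
    out = s.copy()
    chain = out.chain(chain_id)
    aminos = chain.amino_residues()
    if not aminos:
        raise ChemistryError(f"chain {chain_id} has no amino acids to extend")
    if end == "C":
        last = aminos[-1]
        seg_chain = build_peptide(
            chain_letter(last.name) + residues, "extended", cterm_carboxyl=True
        )
        tgt = np.array([last.atom(a).coords for a in BACKBONE_FRAME])
        mob = np.array([seg_chain.residues[0].atom(a).coords for a in BACKBONE_FRAME])
        tr, _ = superpose(mob, tgt)
        # the old terminal residue becomes internal: carbonyl re-oriented, OXT dropped
        seg0 = seg_chain.residues[0]
        if last.has_atom("O"):
            last.atom("O").coords = tr.apply(seg0.atom("O").coords[None, :])[0]
        for name in ("OXT", "HXT"):
            if last.has_atom(name):
                last.remove_atom(name)
        insert_at = chain.residues.index(last) + 1
        new_residues = []
        for i, seg_res in enumerate(seg_chain.residues[1:], start=1):
            seg_res.seq_num = last.seq_num + i
            for a in seg_res.atoms:
                a.coords = tr.apply(a.coords[None, :])[0]
            new_residues.append(seg_res)
        chain.residues[insert_at:insert_at] = new_residues
    else:
        first = aminos[0]
        seg_chain = build_peptide(
            residues + chain_letter(first.name), "extended", cterm_carboxyl=False
        )
        tgt = np.array([first.atom(a).coords for a in BACKBONE_FRAME])
        mob = np.array([seg_chain.residues[-1].atom(a).coords for a in BACKBONE_FRAME])
        tr, _ = superpose(mob, tgt)
        for name in ("H2",):
            if first.has_atom(name):
                first.remove_atom(name)
        new_residues = []
        for i, seg_res in enumerate(seg_chain.residues[:-1]):
            seg_res.seq_num = first.seq_num - (len(seg_chain.residues) - 1) + i
            for a in seg_res.atoms:
                a.coords = tr.apply(a.coords[None, :])[0]
            new_residues.append(seg_res)
        idx = chain.residues.index(first)
        chain.residues[idx:idx] = new_residues
    out.renumber_serials()
    return out


def chain_letter(name3: str) -> str:
    from .model import THREE_TO_ONE

    return THREE_TO_ONE[name3]


# ---------------------------------------------------------------------------
# Disulfides
# ---------------------------------------------------------------------------

def set_disulfide(
    s: Structure,
    cys_a: tuple[str, int],
    cys_b: tuple[str, int],
    present: bool = True,
) -> Structure:
    """Form (or remove) a disulfide between two cysteines.

    Forming records the SG-SG link and removes both HG hydrogens (when
    present); removing restores them if the residues carry hydrogens.  An
    SG-SG distance above 2.5 A triggers a geometry warning (regularization
    will close the bond); above 8 A it is an error.
    """
    out = s.copy()
    refs = []
    for cid, num in (cys_a, cys_b):
        res = out.chain(cid).residue(num)
        if res.name != "CYS":
            raise ChemistryError(f"residue {num} of chain {cid} is {res.name}, not CYS")
        refs.append(AtomRef(cid, num, res.icode, "SG"))
    link = CovalentLink(refs[0], refs[1], "disulfide")
    d = float(np.linalg.norm(out.atom(refs[0]).coords - out.atom(refs[1]).coords))
    if present:
        if d > 8.0:
            raise GeometryError(f"SG-SG distance {d:.2f} A too large to form a disulfide")
        if d > 2.5:
            warnings.warn(
                f"SG-SG distance {d:.2f} A > 2.5 A; recording link, regularization will close it"
            )
        if link not in out.links:
            out.links.append(link)
        for (cid, num) in (cys_a, cys_b):
            res = out.chain(cid).residue(num)
            if res.has_atom("HG"):
                res.remove_atom("HG")
    else:
        out.remove_link(link)
        for (cid, num) in (cys_a, cys_b):
            chain = out.chain(cid)
            res = chain.residue(num)
            still = any(
                l.link_type == "disulfide"
                and any(
                    r.chain_id == cid and r.seq_num == num for r in (l.atom_a, l.atom_b)
                )
                for l in out.links
            )
            if not still and any(a.element == "H" for a in res.atoms):
                aminos = chain.amino_residues()
                idx = chain.residues.index(res)
                prev_c = (
                    chain.residues[idx - 1].atom("C").coords
                    if idx > 0 and chain.residues[idx - 1].has_atom("C")
                    else None
                )
                place_residue_hydrogens(
                    out, cid, res, nterm=res is aminos[0], cterm=res is aminos[-1],
                    prev_c=prev_c,
                )
    return out


# ---------------------------------------------------------------------------
# Five-part assembly
# ---------------------------------------------------------------------------

@dataclass
class AssemblyPart:
    """One source fragment: its structure, how its chains map onto the target
    chain names (H/L/V/M), and which target residue ranges it owns in the
    final model.  Residues present in the part but outside its owned ranges
    exist only to define junctions."""

    name: str
    structure: Structure
    chain_map: dict[str, str]
    owned: dict[str, list[tuple[int, int]]]


@dataclass
class Junction:
    """Shared residues between two parts used for superposition: a list of
    (target chain id, residue number) whose backbone N/CA/C exist in both."""

    part_a: str
    part_b: str
    shared: list[tuple[str, int]]


@dataclass
class AssemblyPlan:
    parts: list[AssemblyPart]
    junctions: list[Junction]
    scaffold: str
    chain_order: list[str] = field(default_factory=lambda: ["H", "L", "V", "M"])

    def part(self, name: str) -> AssemblyPart:
        for p in self.parts:
            if p.name == name:
                return p
        raise AssemblyError(f"no part named {name!r}")


JUNCTION_RMSD_GATE = 2.0  # Angstrom


def assemble(plan: AssemblyPlan) -> Structure:
    """Graft the plan's parts into one structure.

    The scaffold part (the hinge donor) keeps its coordinates; every other
    part is rigidly superposed onto already-placed coordinates through its
    junction residues' backbone atoms (gate: RMSD <= 2 A), then contributes
    exactly the residues it owns.  Covalent links whose atoms both land in
    the output are carried over (deduplicated).
    """
    names = [p.name for p in plan.parts]
    if plan.scaffold not in names:
        raise AssemblyError(f"scaffold {plan.scaffold!r} is not a part")
    adj: dict[str, list[Junction]] = {n: [] for n in names}
    for j in plan.junctions:
        adj[j.part_a].append(j)
        adj[j.part_b].append(j)

    placed: dict[str, Structure] = {}
    # backbone coords of every residue of placed parts, keyed by target ref
    bank: dict[tuple[str, int, str], np.ndarray] = {}

    def register(part: AssemblyPart, st: Structure) -> None:
        placed[part.name] = st
        for src_chain, tgt_chain in part.chain_map.items():
            if not st.has_chain(src_chain):
                continue
            for r in st.chain(src_chain).residues:
                key = (tgt_chain, r.seq_num, r.icode)
                if key in bank:
                    continue
                if all(r.has_atom(a) for a in BACKBONE_FRAME):
                    bank[key] = np.array([r.atom(a).coords for a in BACKBONE_FRAME])

    scaffold = plan.part(plan.scaffold)
    register(scaffold, scaffold.structure.copy())
    queue = [plan.scaffold]
    while queue:
        cur = queue.pop(0)
        for j in adj[cur]:
            other = j.part_b if j.part_a == cur else j.part_a
            if other in placed:
                continue
            part = plan.part(other)
            inv = {v: k for k, v in part.chain_map.items()}
            mobile, target = [], []
            for tgt_chain, num in j.shared:
                key = (tgt_chain, num, "")
                if key not in bank:
                    raise AssemblyError(
                        f"junction {j.part_a}/{j.part_b}: residue {tgt_chain}{num} "
                        "not yet placed"
                    )
                src_chain = inv.get(tgt_chain)
                if src_chain is None or not part.structure.has_chain(src_chain):
                    raise AssemblyError(
                        f"part {other}: no source chain for target {tgt_chain}"
                    )
                res = part.structure.chain(src_chain).residue(num)
                mobile.append(np.array([res.atom(a).coords for a in BACKBONE_FRAME]))
                target.append(bank[key])
            if len(mobile) < 1 or sum(m.shape[0] for m in mobile) < 9:
                raise AssemblyError(
                    f"junction {j.part_a}/{j.part_b}: need >= 3 shared residues"
                )
            tr, rmsd = superpose(np.vstack(mobile), np.vstack(target))
            if rmsd > JUNCTION_RMSD_GATE:
                raise AssemblyError(
                    f"junction {j.part_a}/{j.part_b}: backbone RMSD {rmsd:.2f} A "
                    f"exceeds the {JUNCTION_RMSD_GATE} A gate (parts incompatible)"
                )
            register(part, tr.transform_structure(part.structure))
            queue.append(other)
    missing = [n for n in names if n not in placed]
    if missing:
        raise AssemblyError(f"parts not connected to the scaffold: {missing}")

    # merge owned residues
    out = Structure()
    chains: dict[str, Chain] = {}
    for part in plan.parts:
        st = placed[part.name]
        inv = {v: k for k, v in part.chain_map.items()}
        for tgt_chain, ranges in part.owned.items():
            src = inv.get(tgt_chain)
            if src is None or not st.has_chain(src):
                raise AssemblyError(f"part {part.name}: missing source chain for {tgt_chain}")
            chain = chains.setdefault(tgt_chain, Chain(id=tgt_chain))
            for r in st.chain(src).residues:
                if any(lo <= r.seq_num <= hi for lo, hi in ranges):
                    if any(x.seq_num == r.seq_num and x.icode == r.icode for x in chain.residues):
                        raise AssemblyError(
                            f"residue {tgt_chain}{r.seq_num} owned by two parts"
                        )
                    chain.residues.append(r)
    for chain in chains.values():
        chain.residues.sort(key=lambda r: (r.seq_num, r.icode))
    order = [c for c in plan.chain_order if c in chains]
    order += [c for c in sorted(chains) if c not in order]
    out.chains = [chains[c] for c in order]

    # carry links
    for part in plan.parts:
        st = placed[part.name]
        for link in st.links:
            refs = []
            ok = True
            for ref in (link.atom_a, link.atom_b):
                tgt = part.chain_map.get(ref.chain_id)
                if tgt is None:
                    ok = False
                    break
                new = AtomRef(tgt, ref.seq_num, ref.icode, ref.atom_name)
                if not out.has_atom(new):
                    ok = False
                    break
                refs.append(new)
            if ok:
                nl = CovalentLink(refs[0], refs[1], link.link_type)
                if nl not in out.links:
                    out.links.append(nl)
    out.renumber_serials()
    out.validate()
    return out
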
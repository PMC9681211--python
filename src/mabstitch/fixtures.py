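"""Synthetic test inputs: ideal peptides, paired-CPPC hinges, C2 dimers,
five-part toy assembly plans, and Gaussian perturbations.

Every generator is deterministic given its arguments (and seed, where
randomness is involved), so fixtures can stand in for crystal-structure
inputs in fully offline tests.  The stand-ins are idealized peptide
geometry, not antibody folds: they exercise bookkeeping, topology and
rigid-body machinery, not biology.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .assembly import AssemblyPart, AssemblyPlan, Junction, set_disulfide
from .builder import build_peptide
from .errors import ChemistryError
from .geometry import RigidTransform, random_rigid_transform
from .model import Chain, Structure


def make_ideal_peptide(
    sequence: str,
    conformation: str = "extended",
    chain_id: str = "A",
    start_num: int = 1,
    pca_nterm: bool = False,
    cterm_carboxyl: bool = False,
) -> Structure:
    """Single-chain ideal-geometry peptide (heavy atoms; see add_hydrogens).

    By default the C-terminus is left as a bare carbonyl ("G" gives exactly
    N, CA, C, O); pass `cterm_carboxyl=True` for the full COOH group."""
    chain = build_peptide(
        sequence, conformation, chain_id=chain_id, start_num=start_num,
        pca_nterm=pca_nterm, cterm_carboxyl=cterm_carboxyl,
    )
    s = Structure(chains=[chain])
    s.renumber_serials()
    return s


SS_TARGET = 2.05  # Angstrom


def make_paired_hinge(
    core: str = "CPPC",
    flank_n: str = "",
    flank_c: str = "",
    chain_ids: tuple[str, str] = ("A", "B"),
) -> Structure:
    """Two identical hinge chains with both inter-chain disulfides formed.

    The second chain is the first translated so that matching Cys SG atoms
    sit exactly 2.05 A apart, then flipped 180 degrees about the SG-SG line
    so the backbones face away from each other.  Both disulfide links are
    recorded (and would survive a round trip through the PDB writer).
    """
    if core.count("C") < 2:
        raise ChemistryError("hinge core must contain at least two cysteines")
    seq = flank_n + core + flank_c
    chain_a = build_peptide(seq, "extended", chain_id=chain_ids[0])
    sa = Structure(chains=[chain_a])

    cys_nums = [
        r.seq_num for r in chain_a.residues if r.name == "CYS"
    ]
    first_core_cys = len(flank_n) + 1 + core.index("C")
    last_core_cys = len(flank_n) + 1 + core.rindex("C")
    sg1 = chain_a.residue(first_core_cys).atom("SG").coords
    sg2 = chain_a.residue(last_core_cys).atom("SG").coords
    e = sg2 - sg1
    e /= np.linalg.norm(e)
    body = np.mean([a.coords for r in chain_a.residues for a in r.atoms], axis=0)
    v = body - 0.5 * (sg1 + sg2)
    v_perp = v - (v @ e) * e
    if np.linalg.norm(v_perp) < 1e-9:
        v_perp = np.cross(e, [0.0, 0.0, 1.0])
        if np.linalg.norm(v_perp) < 1e-9:
            v_perp = np.cross(e, [0.0, 1.0, 0.0])
    u = -v_perp / np.linalg.norm(v_perp)  # away from chain A's body

    # copy, shift SGs across, rotate the body 180 deg about the new SG line
    rot180 = Rotation.from_rotvec(np.pi * e).as_matrix()
    pivot = sg1 + SS_TARGET * u
    shift = RigidTransform(np.eye(3), SS_TARGET * u)
    flip = RigidTransform(rot180, pivot - rot180 @ pivot)
    tr = flip.compose(shift)

    chain_b = Chain(id=chain_ids[1])
    for r in chain_a.residues:
        import copy as _c

        rb = _c.deepcopy(r)
        for a in rb.atoms:
            a.coords = tr.apply(a.coords[None, :])[0]
        chain_b.residues.append(rb)
    s = Structure(chains=[chain_a, chain_b])
    s.renumber_serials()
    for num in (first_core_cys, last_core_cys):
        s = set_disulfide(s, (chain_ids[0], num), (chain_ids[1], num), present=True)
    return s


def make_c2_dimer(
    monomer: Structure,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    point: np.ndarray = (0.0, 0.0, 0.0),
    angle: float = 180.0,
    second_chain_suffix: str | None = None,
) -> Structure:
    """Dimer built by rotating a copy of `monomer` about an axis.

    Chain ids of the copy are remapped to the next free single characters
    (or lowercase of the original when available)."""
    if not monomer.chains or monomer.n_atoms() == 0:
        raise ChemistryError("empty monomer")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    point = np.asarray(point, dtype=float)
    R = Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
    tr = RigidTransform(R, point - R @ point)
    copy2 = tr.transform_structure(monomer)
    used = {c.id for c in monomer.chains}
    out = monomer.copy()
    for c in copy2.chains:
        new_id = c.id.lower() if c.id.lower() not in used else None
        if new_id is None:
            for cand in "ZYXWVUTSRQPONMLKJIHGFEDCBA0123456789":
                if cand not in used:
                    new_id = cand
                    break
        used.add(new_id)
        c.id = new_id
        out.chains.append(c)
    out.renumber_serials()
    return out


# ---------------------------------------------------------------------------
# Five-part toy plan
# ---------------------------------------------------------------------------

TOY_HEAVY = "GAVLGCPPCGSTGAVLGSTAGSTA"  # 24 residues, CPPC-like core at 6-9
TOY_LIGHT = "ASTGAVLG"  # 8 residues

#: target-chain residue spans of the toy heavy chain, mimicking
#: Fab / upper hinge (with core) / lower hinge / Fc
TOY_SPANS = {"fab": (1, 5), "upper": (6, 10), "lower": (11, 16), "fc": (17, 24)}


def make_five_part_plan(
    seed: int = 0,
    heavy_seq: str = TOY_HEAVY,
    light_seq: str = TOY_LIGHT,
    spans: dict[str, tuple[int, int]] | None = None,
    junction_width: int = 3,
) -> tuple[AssemblyPlan, Structure]:
    """A five-part plan (two Fabs, Fc, upper hinge + core, lower hinge) cut
    from a known ground-truth assembly, plus that ground truth.

    The ground truth is built deterministically; each non-scaffold part is
    then displaced by a random rigid transform drawn from `seed`, so
    assembling the plan must exactly invert those displacements.
    """
    spans = dict(spans or TOY_SPANS)
    rng = np.random.default_rng(seed)

    # ground truth: four chains laid out side by side
    truth = Structure()
    offsets = {"H": [0, 0, 0], "L": [0, 12, 0], "V": [0, -40, 0], "M": [0, -52, 0]}
    for cid, seq in (("H", heavy_seq), ("L", light_seq), ("V", heavy_seq), ("M", light_seq)):
        chain = build_peptide(seq, "extended", chain_id=cid)
        for r in chain.residues:
            for a in r.atoms:
                a.coords = a.coords + np.array(offsets[cid], dtype=float)
        truth.chains.append(chain)
    truth.renumber_serials()

    w = junction_width

    def cut(name: str, selections: dict[str, tuple[int, int]], owned: dict) -> AssemblyPart:
        st = Structure()
        for cid, (lo, hi) in selections.items():
            src = truth.chain(cid)
            chain = Chain(id=cid)
            import copy as _c

            for r in src.residues:
                if lo <= r.seq_num <= hi:
                    chain.residues.append(_c.deepcopy(r))
            st.chains.append(chain)
        return AssemblyPart(name=name, structure=st, chain_map={c.id: c.id for c in st.chains}, owned=owned)

    fab_hi = spans["fab"][1]
    upper = spans["upper"]
    lower = spans["lower"]
    fc = spans["fc"]
    nl = len(light_seq)

    parts = [
        cut(
            "upper_hinge",
            {"H": (upper[0], upper[1] + w), "V": (upper[0], upper[1] + w)},
            {"H": [upper], "V": [upper]},
        ),
        cut(
            "fab1",
            {"H": (1, fab_hi + w), "L": (1, nl)},
            {"H": [(1, fab_hi)], "L": [(1, nl)]},
        ),
        cut(
            "fab2",
            {"V": (1, fab_hi + w), "M": (1, nl)},
            {"V": [(1, fab_hi)], "M": [(1, nl)]},
        ),
        cut(
            "lower_hinge",
            {"H": (lower[0] - w, lower[1] + w), "V": (lower[0] - w, lower[1] + w)},
            {"H": [lower], "V": [lower]},
        ),
        cut(
            "fc",
            {"H": (fc[0] - w, fc[1]), "V": (fc[0] - w, fc[1])},
            {"H": [fc], "V": [fc]},
        ),
    ]
    # overlap between owned spans and junction-only residues defines junctions
    junctions = [
        Junction("upper_hinge", "fab1", [("H", n) for n in range(upper[0], upper[0] + w)]),
        Junction("upper_hinge", "fab2", [("V", n) for n in range(upper[0], upper[0] + w)]),
        Junction(
            "upper_hinge",
            "lower_hinge",
            [(c, n) for c in ("H", "V") for n in range(lower[0] - w, lower[0])],
        ),
        Junction(
            "lower_hinge",
            "fc",
            [(c, n) for c in ("H", "V") for n in range(lower[1] + 1, lower[1] + 1 + w)],
        ),
    ]
    # junction residues live in the neighbouring part's owned span; make sure
    # each junction's residues are owned by exactly one of the two parts
    for part in parts[1:]:
        tr = random_rigid_transform(rng)
        part.structure = tr.transform_structure(part.structure)

    plan = AssemblyPlan(parts=parts, junctions=junctions, scaffold="upper_hinge")
    return plan, truth


def perturb(s: Structure, sigma: float, seed: int) -> Structure:
    """I.i.d. Gaussian displacement of every coordinate; deterministic per seed."""
    if sigma < 0:
        raise ChemistryError("sigma must be >= 0")
    out = s.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    xyz = out.coords()
    out.set_coords(xyz + rng.normal(0.0, sigma, size=xyz.shape))
    return out
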
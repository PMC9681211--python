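"""Canonical reference frame and whole-model metrics.

The deposited model's convention: the Fc two-fold (dyad) axis lies along z
with the Fc body below the xy plane, and the origin sits at the midpoint
between the CA atoms of the two Pro241 residues at the top of the Fc.  The
in-plane orientation is fixed by sending the centroid of chain H's Fab lobe
to positive x, which the text leaves free but makes output deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, SelectionError, SymmetryError
from .geometry import RigidTransform, superpose
from .model import ATOMIC_MASS, Structure

DYAD_TOLERANCE_DEG = 10.0


@dataclass
class DyadAxis:
    direction: np.ndarray  # unit vector
    point: np.ndarray  # a point on the axis
    rotation_angle: float  # degrees, close to 180 for a true dyad

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise GeometryError("dyad direction must be a unit vector")


def compute_dyad(coords_a: np.ndarray, coords_b: np.ndarray) -> DyadAxis:
    """Two-fold axis relating two matched copies (e.g. the Fc heavy chains).

    Superposes a onto b, extracts the rotation angle and axis, and raises
    SymmetryError if the angle deviates from 180 degrees by more than 10.
    The axis point is the projection of the combined centroid onto the
    fixed line of the transform.
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    tr, _ = superpose(coords_a, coords_b)
    rot = Rotation.from_matrix(tr.rotation)
    angle = float(np.degrees(np.linalg.norm(rot.as_rotvec())))
    if abs(angle - 180.0) > DYAD_TOLERANCE_DEG:
        raise SymmetryError(
            f"rotation angle {angle:.1f} deg is not a two-fold (>{DYAD_TOLERANCE_DEG} "
            "deg from 180)"
        )
    rv = rot.as_rotvec()
    direction = rv / np.linalg.norm(rv)
    # fixed line of x -> Rx + t: minimum-norm solution of (R - I) p = -t
    A = tr.rotation - np.eye(3)
    p0, *_ = np.linalg.lstsq(A, -tr.translation, rcond=None)
    centroid = 0.5 * (coords_a.mean(axis=0) + coords_b.mean(axis=0))
    point = p0 + direction * float((centroid - p0) @ direction)
    return DyadAxis(direction=direction, point=point, rotation_angle=angle)


@dataclass
class CanonicalFrame:
    transform: RigidTransform


def canonical_frame(
    s: Structure,
    dyad: DyadAxis,
    pro_pair: tuple[tuple[str, int], tuple[str, int]],
    fc_selection: list[tuple[str, tuple[int, int]]],
    fab_selection: list[tuple[str, tuple[int, int]]] | None = None,
) -> tuple[RigidTransform, Structure]:
    """Rigid transform into the canonical frame, and the framed structure.

    `pro_pair` names the two Pro residues whose CA midpoint becomes the
    origin; `fc_selection` / `fab_selection` are (chain, (lo, hi)) residue
    ranges used to resolve the z sign (Fc centre of mass below the plane)
    and the x direction (first chain's Fab centroid at positive x).
    """
    cas = []
    for cid, num in pro_pair:
        res = s.chain(cid).residue(num)
        if not res.has_atom("CA"):
            raise SelectionError(f"residue {cid}{num} lacks a CA atom")
        cas.append(res.atom("CA").coords)
    origin = 0.5 * (cas[0] + cas[1])

    z = dyad.direction / np.linalg.norm(dyad.direction)
    fc_com = _selection_center(s, fc_selection, mass_weighted=True)
    if float((fc_com - origin) @ z) > 0:
        z = -z  # Fc body must end up below the xy plane

    if fab_selection is None:
        v = _whole_center(s) - origin
    else:
        v = _selection_center(s, fab_selection, mass_weighted=False) - origin
    x = v - (v @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        # degenerate in-plane reference: fall back to any perpendicular
        x = np.cross(z, [1.0, 0.0, 0.0])
        if np.linalg.norm(x) < 1e-9:
            x = np.cross(z, [0.0, 1.0, 0.0])
        nx = np.linalg.norm(x)
    x /= nx
    y = np.cross(z, x)
    basis = np.vstack([x, y, z])  # rows
    tr = RigidTransform(basis, -basis @ origin)
    return tr, tr.transform_structure(s)


def _selection_center(
    s: Structure, selection: list[tuple[str, tuple[int, int]]], mass_weighted: bool
) -> np.ndarray:
    pts, w = [], []
    for cid, (lo, hi) in selection:
        for r in s.chain(cid).residues:
            if lo <= r.seq_num <= hi:
                for a in r.atoms:
                    pts.append(a.coords)
                    w.append(ATOMIC_MASS[a.element] if mass_weighted else 1.0)
    if not pts:
        raise SelectionError(f"selection {selection} matched no atoms")
    pts = np.array(pts)
    w = np.array(w)
    return (w[:, None] * pts).sum(axis=0) / w.sum()


def _whole_center(s: Structure) -> np.ndarray:
    return s.coords().mean(axis=0)


def radius_of_gyration(s: Structure, weighting: str = "mass") -> float:
    """Radius of gyration in nm: sqrt(sum w |r - rbar|^2 / sum w)."""
    if weighting not in ("mass", "uniform"):
        raise GeometryError(f"unknown weighting {weighting!r}")
    xyz = s.coords()
    if xyz.shape[0] == 0:
        raise GeometryError("empty structure")
    w = s.masses() if weighting == "mass" else np.ones(xyz.shape[0])
    center = (w[:, None] * xyz).sum(axis=0) / w.sum()
    d2 = np.einsum("ij,ij->i", xyz - center, xyz - center)
    rg_angstrom = float(np.sqrt((w * d2).sum() / w.sum()))
    return rg_angstrom / 10.0


def lobe_extent(
    s: Structure, lobes: dict[str, list[tuple[str, tuple[int, int]]]]
) -> dict[str, float]:
    """Per-lobe maximum atom distance from the origin, in nm (canonical
    frame assumed already applied)."""
    out = {}
    for name, selection in lobes.items():
        best = None
        for cid, (lo, hi) in selection:
            for r in s.chain(cid).residues:
                if lo <= r.seq_num <= hi:
                    for a in r.atoms:
                        d = float(np.linalg.norm(a.coords))
                        if best is None or d > best:
                            best = d
        if best is None:
            raise SelectionError(f"lobe {name!r}: empty selection")
        out[name] = best / 10.0
    return out


def hinge_bend_angle(s: Structure, chain_id: str, window: list[int]) -> float:
    """Bend angle (degrees) at the centre of a residue window: the angle
    between best-fit lines through the CA atoms of the two window halves,
    measured like a bond angle at the bend (collinear path -> 180)."""
    cas = []
    chain = s.chain(chain_id)
    for num in window:
        res = chain.residue(num)
        if not res.has_atom("CA"):
            raise GeometryError(f"residue {chain_id}{num} lacks CA")
        cas.append(res.atom("CA").coords)
    cas = np.array(cas)
    half = len(cas) // 2
    if half < 3:
        raise GeometryError("need at least 3 CA atoms per window half")
    v1 = _fit_direction(cas[:half])
    v2 = _fit_direction(cas[len(cas) - half:])
    cosang = np.clip(float((-v1) @ v2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _fit_direction(points: np.ndarray) -> np.ndarray:
    """Principal direction of a CA run, oriented along the sequence."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    d = vt[0]
    if float(d @ (points[-1] - points[0])) < 0:
        d = -d
    return d / np.linalg.norm(d)
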
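"""Rigid-body transforms and least-squares superposition (Kabsch).

The rotation part of every :class:`RigidTransform` is a proper rotation
(orthonormal, det = +1); reflections are never produced, so chirality is
preserved by construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError
from .model import Structure


@dataclass
class RigidTransform:
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise GeometryError("rigid transform has wrong shapes")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        det = np.linalg.det(self.rotation)
        if err > 1e-9 or abs(det - 1.0) > 1e-9:
            raise GeometryError(
                f"rotation not orthonormal/proper (orthogonality err {err:.2e}, det {det:.12f})"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def transform_structure(self, s: Structure) -> Structure:
        out = s.copy()
        out.set_coords(self.apply(out.coords()))
        return out

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - np.eye(3)).max() <= tol
            and np.abs(self.translation).max() <= tol
        )


def superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of `mobile` onto `target`.

    Returns the proper-rotation transform T minimizing the (weighted) RMSD of
    ``T(mobile)`` to ``target``, and that RMSD in the same length units.

    Requires >= 3 points that are not all collinear.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("superpose needs matching (n, 3) point lists")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superpose needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("bad superposition weights")
    wn = w / w.sum()
    cm = wn @ mobile
    ct = wn @ target
    mc = mobile - cm
    tc = target - ct
    # collinearity check on the mobile set: rank of centered coords must be >= 2
    if np.linalg.matrix_rank(mc * np.sqrt(wn)[:, None], tol=1e-8) < 2:
        raise GeometryError("superpose points are collinear (or coincident)")
    rot, _ = Rotation.align_vectors(tc, mc, weights=w)
    R = rot.as_matrix()
    t = ct - R @ cm
    tr = RigidTransform(R, t)
    d = tr.apply(mobile) - target
    rmsd = float(np.sqrt(np.sum(wn * np.einsum("ij,ij->i", d, d))))
    return tr, rmsd


def random_rigid_transform(rng: np.random.Generator, max_translation: float = 20.0) -> RigidTransform:
    """Uniform random proper rotation plus a bounded random translation."""
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(R, t)
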
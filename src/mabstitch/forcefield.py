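"""Surrogate molecular-mechanics terms and the staged minimizer.

The potential is deliberately simple -- harmonic bonds, harmonic angles and a
purely repulsive soft-sphere term with 1-2/1-3 exclusions -- because its job
is to relieve splice and mutation strain and restore ideal local geometry,
not to reproduce a biomolecular force field's energies.  Energies are in
arbitrary units; ideal bond lengths and angles come from the same CCD
templates used to build residues, so freshly built ideal-geometry fragments
sit at (or extremely near) the potential's minimum.

Minimization reproduces the staged protocol: a fixed number of steepest-
descent steps with backtracking line search, then a fixed number of
Polak-Ribiere conjugate-gradient steps with restarts, no early stopping, so
the trace length is deterministic.  Step sizes come from a directional
curvature estimate (exact on quadratics, so CG inherits its finite-step
convergence property) guarded by backtracking.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .bondgraph import INTER_BOND_LENGTH, covalent_bonds
from .errors import MinimizationError, TopologyError
from .model import AtomRef, Structure
from .templates import residue_template, template_angle

BOND_K = 300.0  # per A^2
ANGLE_K = 80.0  # per rad^2
REPULSION_K = 50.0  # per A^2

#: per-element contact radii (A); soft-sphere diameter = scale * (r_i + r_j)
CONTACT_RADIUS = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}
CONTACT_SCALE = 0.75

ANGLE_CA_C_N = np.deg2rad(116.2)
ANGLE_C_N_CA = np.deg2rad(121.7)
ANGLE_C_N_CD = np.deg2rad(125.0)  # proline imide
ANGLE_AMIDE_H = np.deg2rad(119.15)
ANGLE_SS = np.deg2rad(104.0)
ANGLE_GLYCOSIDIC = np.deg2rad(117.0)
ANGLE_TETRAHEDRAL = np.deg2rad(109.47)


@dataclass
class ForceFieldTerms:
    refs: list[AtomRef]
    bond_idx: np.ndarray  # (nb, 2)
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angle_idx: np.ndarray  # (na, 3), center second
    angle_t0: np.ndarray
    angle_k: np.ndarray
    sigma: np.ndarray  # per-atom contact radius (already scaled)
    exclusions: set[int] = field(default_factory=set)  # i * n + j, i < j
    n_atoms: int = 0

    # ---- evaluation ---------------------------------------------------
    def energy_gradient(self, xyz: np.ndarray) -> tuple[float, np.ndarray]:
        x = xyz.reshape(-1, 3)
        if x.shape[0] != self.n_atoms:
            raise MinimizationError("coordinate/topology size mismatch")
        e = 0.0
        g = np.zeros_like(x)

        if len(self.bond_idx):
            i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
            d = x[i] - x[j]
            r = np.linalg.norm(d, axis=1)
            dr = r - self.bond_r0
            e += float(np.sum(self.bond_k * dr**2))
            f = (2.0 * self.bond_k * dr / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(g, i, f)
            np.add.at(g, j, -f)

        if len(self.angle_idx):
            ii, jj, kk = (self.angle_idx[:, c] for c in range(3))
            u = x[ii] - x[jj]
            v = x[kk] - x[jj]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            cos = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
            theta = np.arccos(cos)
            dt = theta - self.angle_t0
            e += float(np.sum(self.angle_k * dt**2))
            sin = np.sqrt(np.maximum(1.0 - cos**2, 1e-12))
            coef = 2.0 * self.angle_k * dt
            gi = (coef / (nu * sin))[:, None] * (cos[:, None] * uh - vh)
            gk = (coef / (nv * sin))[:, None] * (cos[:, None] * vh - uh)
            np.add.at(g, ii, gi)
            np.add.at(g, kk, gk)
            np.add.at(g, jj, -(gi + gk))

        if self.n_atoms > 1 and np.any(self.sigma > 0):
            cutoff = 2.0 * float(self.sigma.max())
            tree = cKDTree(x)
            pairs = tree.query_pairs(cutoff, output_type="ndarray")
            if len(pairs):
                i, j = pairs[:, 0], pairs[:, 1]
                keys = i.astype(np.int64) * self.n_atoms + j
                mask = ~np.isin(keys, self._excl_array())
                i, j = i[mask], j[mask]
                if len(i):
                    sij = self.sigma[i] + self.sigma[j]
                    d = x[i] - x[j]
                    r = np.linalg.norm(d, axis=1)
                    viol = r < sij
                    if np.any(viol):
                        i, j, r, d, sij = i[viol], j[viol], r[viol], d[viol], sij[viol]
                        dr = sij - r
                        e += float(np.sum(REPULSION_K * dr**2))
                        f = (-2.0 * REPULSION_K * dr / np.maximum(r, 1e-12))[:, None] * d
                        np.add.at(g, i, f)
                        np.add.at(g, j, -f)
        return e, g.ravel()

    def _excl_array(self) -> np.ndarray:
        if not hasattr(self, "_excl_cache"):
            self._excl_cache = np.fromiter(self.exclusions, dtype=np.int64, count=len(self.exclusions))
            self._excl_cache.sort()
        return self._excl_cache


def _inter_angle_ideal(center_res_name: str, names: tuple[str, str, str], kinds: tuple[str, str]) -> float:
    """Ideal angle for a bond pair not fully contained in one residue."""
    a, b, c = names
    if "disulfide" in kinds:
        return ANGLE_SS
    if "glycosidic" in kinds or "n_glycosidic" in kinds:
        if b.startswith("O") or b == "ND2":
            return ANGLE_GLYCOSIDIC
        return ANGLE_TETRAHEDRAL
    # peptide-bond angles
    key = {a, c}
    if b == "C" and key == {"CA", "N"}:
        return ANGLE_CA_C_N
    if b == "C" and key == {"O", "N"}:
        # planar carbonyl: O-C-N closes the triangle around sp2 C
        tco = template_angle(center_res_name, "CA", "C", "O")
        return 2.0 * np.pi - ANGLE_CA_C_N - tco
    if b == "N" and key == {"C", "CA"}:
        return ANGLE_C_N_CA
    if b == "N" and key == {"C", "CD"}:
        return ANGLE_C_N_CD
    if b == "N" and key == {"C", "H"}:
        return ANGLE_AMIDE_H
    return ANGLE_TETRAHEDRAL


def build_topology(s: Structure) -> ForceFieldTerms:
    """Derive bonded terms and exclusions from templates plus explicit links."""
    refs = [ref for ref, _ in s.iter_refs()]
    index = {ref: i for i, ref in enumerate(refs)}
    elements = {ref: a.element for ref, a in s.iter_refs()}
    n = len(refs)

    res_of = {}
    name_of = {}
    for c in s.chains:
        for r in c.residues:
            for a in r.atoms:
                ref = AtomRef(c.id, r.seq_num, r.icode, a.name)
                res_of[ref] = (c.id, r.seq_num, r.icode)
                name_of[ref] = r.name

    bonds = covalent_bonds(s)
    bi, br0, bk = [], [], []
    adj: dict[AtomRef, list[tuple[AtomRef, str]]] = {ref: [] for ref in refs}
    for a, b, kind in bonds:
        if a not in index or b not in index:
            raise TopologyError(f"bond references missing atom: {a} - {b}")
        bi.append((index[a], index[b]))
        if kind == "template":
            t = residue_template(name_of[a])
            br0.append(float(np.linalg.norm(t.coords[a.atom_name] - t.coords[b.atom_name])))
        else:
            br0.append(INTER_BOND_LENGTH[kind])
        bk.append(BOND_K)
        adj[a].append((b, kind))
        adj[b].append((a, kind))

    ai, at0, ak = [], [], []
    for center in refs:
        nbrs = adj[center]
        for p in range(len(nbrs)):
            for q in range(p + 1, len(nbrs)):
                (na, ka), (nc, kc) = nbrs[p], nbrs[q]
                same_res = res_of[na] == res_of[center] == res_of[nc]
                amide_h = (
                    center.atom_name == "N"
                    and "H" in (na.atom_name, nc.atom_name)
                    and name_of[center] != "PCA"
                    and AtomRef(center.chain_id, center.seq_num, center.icode, "H2")
                    not in index
                )
                if amide_h:
                    # planar amide: H sits on the bisector opposite CA and C
                    t0 = ANGLE_AMIDE_H
                elif same_res and ka == kc == "template":
                    t0 = template_angle(
                        name_of[center], na.atom_name, center.atom_name, nc.atom_name
                    )
                else:
                    t0 = _inter_angle_ideal(
                        name_of[center],
                        (na.atom_name, center.atom_name, nc.atom_name),
                        (ka, kc),
                    )
                ai.append((index[na], index[center], index[nc]))
                at0.append(t0)
                ak.append(ANGLE_K)

    # 1-2 / 1-3 exclusions from graph distance
    excl: set[int] = set()

    def ekey(i: int, j: int) -> int:
        return (i * n + j) if i < j else (j * n + i)

    neighbor_idx: dict[int, set[int]] = {i: set() for i in range(n)}
    for (i, j) in bi:
        neighbor_idx[i].add(j)
        neighbor_idx[j].add(i)
        excl.add(ekey(i, j))
    for j, nbrs in neighbor_idx.items():
        nl = sorted(nbrs)
        for p in range(len(nl)):
            for q in range(p + 1, len(nl)):
                excl.add(ekey(nl[p], nl[q]))

    sigma = np.array([CONTACT_SCALE * CONTACT_RADIUS[elements[r]] for r in refs])
    return ForceFieldTerms(
        refs=refs,
        bond_idx=np.array(bi, dtype=int).reshape(-1, 2),
        bond_r0=np.array(br0),
        bond_k=np.array(bk),
        angle_idx=np.array(ai, dtype=int).reshape(-1, 3),
        angle_t0=np.array(at0),
        angle_k=np.array(ak),
        sigma=sigma,
        exclusions=excl,
        n_atoms=n,
    )


def energy_and_gradient(s: Structure, ff: ForceFieldTerms) -> tuple[float, np.ndarray]:
    """Energy (arbitrary units) and per-atom gradient (n_atoms, 3)."""
    e, g = ff.energy_gradient(s.coords().ravel())
    return e, g.reshape(-1, 3)


# ---------------------------------------------------------------------------
# Staged minimizer
# ---------------------------------------------------------------------------

@dataclass
class MinimizationTrace:
    steps: list[tuple[int, str, float, float]] = field(default_factory=list)

    def record(self, step: int, phase: str, energy: float, max_grad: float) -> None:
        self.steps.append((step, phase, energy, max_grad))

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def energies(self) -> np.ndarray:
        return np.array([s[2] for s in self.steps])

    @property
    def max_gradients(self) -> np.ndarray:
        return np.array([s[3] for s in self.steps])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "phase", "energy", "max_gradient"])

    def write_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _directional_step(fgrad, x, e0, g, d):
    """Trial step length from directional curvature (exact on quadratics),
    guarded by backtracking so the energy never increases."""
    gd = float(g @ d)
    if gd >= 0.0:
        return 0.0, e0, g
    dn = float(np.linalg.norm(d))
    tau = min(1.0, 0.1 / dn) if dn > 0 else 0.0
    if tau == 0.0:
        return 0.0, e0, g
    _, g_tau = fgrad(x + tau * d)
    curv = float((g_tau - g) @ d) / tau
    alpha = -gd / curv if curv > 1e-14 else tau
    for _ in range(40):
        e_new, g_new = fgrad(x + alpha * d)
        if np.isfinite(e_new) and e_new <= e0:
            return alpha, e_new, g_new
        alpha *= 0.5
    return 0.0, e0, g


def minimize_function(
    x0: np.ndarray, fgrad, n_sd: int = 500, n_cg: int = 500
) -> tuple[np.ndarray, MinimizationTrace]:
    """Fixed-step-count staged minimization of a generic objective.

    `fgrad(x) -> (energy, gradient)`.  Exactly n_sd steepest-descent steps
    (backtracking, energy non-increasing) followed by n_cg Polak-Ribiere
    conjugate-gradient steps with restart on loss of descent.
    """
    x = np.array(x0, dtype=float)
    e, g = fgrad(x)
    if not np.isfinite(e):
        raise MinimizationError("non-finite energy at start")
    trace = MinimizationTrace()
    step = 0
    for _ in range(n_sd):
        step += 1
        d = -g
        alpha, e, g = _directional_step(fgrad, x, e, g, d)
        if alpha > 0:
            x = x + alpha * d
        if not np.isfinite(e):
            raise MinimizationError(f"non-finite energy at step {step}")
        trace.record(step, "SD", e, float(np.abs(g).max(initial=0.0)))
    d = -g
    for _ in range(n_cg):
        step += 1
        if float(g @ d) >= 0.0:
            d = -g  # restart on loss of descent
        alpha, e, g_new = _directional_step(fgrad, x, e, g, d)
        if alpha > 0:
            x = x + alpha * d
        if not np.isfinite(e):
            raise MinimizationError(f"non-finite energy at step {step}")
        denom = float(g @ g)
        beta = max(0.0, float(g_new @ (g_new - g)) / denom) if denom > 0 else 0.0
        d = -g_new + beta * d
        g = g_new
        trace.record(step, "CG", e, float(np.abs(g).max(initial=0.0)))
    return x, trace


def minimize(
    s: Structure, ff: ForceFieldTerms, n_sd: int = 500, n_cg: int = 500
) -> tuple[Structure, MinimizationTrace]:
    """Staged minimization of a structure; returns the relaxed copy and the
    per-step (energy, max |gradient component|) trace of length n_sd + n_cg."""
    x, trace = minimize_function(s.coords().ravel(), ff.energy_gradient, n_sd, n_cg)
    out = s.copy()
    out.set_coords(x.reshape(-1, 3))
    return out, trace
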
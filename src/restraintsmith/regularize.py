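"""Minimal geometry regularizer over a restraint set.

The target is the standard sum of squared, sigma-weighted residuals: bond
(d - ideal)^2/sigma^2, angle and periodic torsion (delta theta)^2/sigma^2
(the torsion residual uses the nearest period-equivalent ideal), plane
terms as the summed squared distances to the current least-squares plane,
and chiral-volume terms (V - V_ideal)^2/sigma_V^2 where the target volume
is derived from the dictionary bond lengths and angles around the centre
(sign handling for 'both' follows the current handedness).  An optional
soft quartic repulsion between non-bonded pairs prevents collapse.

Minimization uses L-BFGS with an Armijo backtracking line search; a
"cycle" is one accepted step, so the recorded target values are
non-increasing by construction.  Atoms outside the moving mask
(zero-occupancy generated hydrogens by default) stay fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._geom import periodic_delta
from .config import Options, covalent_radius
from .errors import ModelError
from .model_io import StructureModel
from .restraints import Restraint, RestraintSet

logger = logging.getLogger("restraintsmith.regularize")

CHIR_SIGMA = 0.2  # Å^3, chiral-volume sigma


@dataclass
class GeometryTarget:
    """A restraint set bound to a coordinate vector."""

    model: StructureModel
    rset: RestraintSet
    weights: dict[str, float] = field(default_factory=dict)
    repulsion: bool = True
    repulsion_scale: float = 0.8
    repulsion_weight: float = 4.0
    moving_mask: np.ndarray | None = None   # bool per atom
    include_zero_occ_h: bool = False

    def __post_init__(self):
        atoms = [a for _, _, a in self.model.all_atoms()]
        self.atoms = atoms
        self.index = {id(a): i for i, a in enumerate(atoms)}
        self.elements = [a.element for a in atoms]
        if self.moving_mask is None:
            self.moving_mask = np.array([
                not (a.is_generated_h and a.occupancy == 0.0) for a in atoms
            ])
        self.terms = []
        bonded: set[frozenset[int]] = set()
        for r in self.rset:
            if not self.include_zero_occ_h and r.zero_occ_h:
                continue
            try:
                idx = tuple(self.index[id(a.site)] for a in r.atoms)
            except KeyError:
                raise ModelError(
                    f"restraint {r.kind} references an atom missing from the "
                    f"model coordinates"
                ) from None
            self.terms.append((r, idx))
            if r.kind == "bond":
                bonded.add(frozenset(idx))
        self.excluded_pairs = _excluded_pairs(bonded, len(atoms))
        self.chir_targets = {
            id(r): _chiral_target(r, self.rset) for r, _ in self.terms
            if r.kind == "chirality"
        }

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def set_coords(self, x: np.ndarray) -> None:
        for a, pos in zip(self.atoms, x):
            a.position = pos.copy()


def _excluded_pairs(bonded: set[frozenset[int]], n: int) -> set[frozenset[int]]:
    """1-2, 1-3 and 1-4 related pairs, from the bond graph."""
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for pair in bonded:
        i, j = tuple(pair)
        adj[i].add(j)
        adj[j].add(i)
    excluded = set(bonded)
    for i in range(n):
        for j in adj[i]:
            for k in adj[j]:
                if k != i:
                    excluded.add(frozenset((i, k)))
                    for l in adj[k]:
                        if l != j and l != i:
                            excluded.add(frozenset((i, l)))
    return excluded


def _chiral_target(r: Restraint, rset: RestraintSet) -> float:
    """Ideal chiral volume from the dictionary bonds and angles around the
    centre; tetrahedral defaults where a value is missing."""
    centre = r.atoms[0]
    dists = []
    angles = {}
    for other in r.atoms[1:]:
        d = 1.5
        for b in rset.of_kind("bond"):
            keys = {a.key() for a in b.atoms}
            if keys == {centre.key(), other.key()} and b.ideal:
                d = b.ideal
        dists.append(d)
    for i in range(3):
        for j in range(i + 1, 3):
            ang = TET = 109.47
            for t in rset.of_kind("angle"):
                if t.atoms[1].key() != centre.key():
                    continue
                outer = {t.atoms[0].key(), t.atoms[2].key()}
                if outer == {r.atoms[1 + i].key(), r.atoms[1 + j].key()} and t.ideal:
                    ang = t.ideal
            angles[(i, j)] = np.radians(ang)
    c1 = np.cos(angles[(0, 1)])
    c2 = np.cos(angles[(0, 2)])
    c3 = np.cos(angles[(1, 2)])
    det = 1 - c1 * c1 - c2 * c2 - c3 * c3 + 2 * c1 * c2 * c3
    vol = dists[0] * dists[1] * dists[2] * np.sqrt(max(det, 0.0))
    if r.sign == "negative":
        vol = -vol
    return vol


def build_target(model: StructureModel, rset: RestraintSet,
                 options: Options | None = None) -> GeometryTarget:
    options = options or Options()
    return GeometryTarget(
        model=model, rset=rset, repulsion=options.repulsion,
        repulsion_scale=options.repulsion_scale,
        repulsion_weight=options.repulsion_weight,
    )


# --- value and gradient ------------------------------------------------------

_DEG = 180.0 / np.pi


def _angle_value_grad(p1, p2, p3):
    u = p1 - p2
    v = p3 - p2
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    cross = np.cross(u, v)
    ncross = np.linalg.norm(cross)
    dot = float(np.dot(u, v))
    theta = np.arctan2(ncross, dot)
    if ncross < 1e-12:
        return np.degrees(theta), np.zeros(3), np.zeros(3), np.zeros(3)
    g1 = np.cross(u, cross) / (nu * nu * ncross)
    g3 = np.cross(cross, v) / (nv * nv * ncross)
    g2 = -g1 - g3
    return np.degrees(theta), g1 * _DEG, g2 * _DEG, g3 * _DEG


def _torsion_value_grad(p1, p2, p3, p4):
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    m1 = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    phi = np.arctan2(y, x)
    # classic analytic dihedral gradient
    sq1 = float(np.dot(n1, n1))
    sq2 = float(np.dot(n2, n2))
    if sq1 < 1e-12 or sq2 < 1e-12:
        z = np.zeros(3)
        return np.degrees(phi), z, z, z
    g1 = nb2 / sq1 * n1
    g4 = -nb2 / sq2 * n2
    d12 = float(np.dot(b1, b2)) / (nb2 * nb2)
    d32 = float(np.dot(b3, b2)) / (nb2 * nb2)
    g2 = -(1.0 + d12) * g1 + d32 * g4
    g3 = d12 * g1 - (1.0 + d32) * g4
    return np.degrees(phi), g1 * _DEG, g2 * _DEG, g3 * _DEG, g4 * _DEG


def evaluate(target: GeometryTarget, coords: np.ndarray,
             per_kind: dict | None = None) -> tuple[float, np.ndarray]:
    """Target value and analytic gradient at ``coords``."""
    x = coords
    if not np.all(np.isfinite(x)):
        raise ModelError("non-finite coordinates passed to the target")
    value = 0.0
    grad = np.zeros_like(x)
    for r, idx in target.terms:
        w = target.weights.get(r.kind, 1.0)
        if r.kind == "bond":
            i, j = idx
            d = x[i] - x[j]
            dist = float(np.linalg.norm(d))
            delta = dist - r.ideal
            value += w * (delta / r.sigma) ** 2
            if dist > 1e-12:
                g = w * 2 * delta / r.sigma ** 2 * d / dist
                grad[i] += g
                grad[j] -= g
            res = delta / r.sigma
        elif r.kind == "angle":
            i, j, k = idx
            ang, g1, g2, g3 = _angle_value_grad(x[i], x[j], x[k])
            delta = ang - r.ideal
            value += w * (delta / r.sigma) ** 2
            c = w * 2 * delta / r.sigma ** 2
            grad[i] += c * g1
            grad[j] += c * g2
            grad[k] += c * g3
            res = delta / r.sigma
        elif r.kind == "torsion":
            i, j, k, l = idx
            phi, g1, g2, g3, g4 = _torsion_value_grad(x[i], x[j], x[k], x[l])
            delta = periodic_delta(phi, r.ideal, r.period)
            value += w * (delta / r.sigma) ** 2
            c = w * 2 * delta / r.sigma ** 2
            grad[i] += c * g1
            grad[j] += c * g2
            grad[k] += c * g3
            grad[l] += c * g4
            res = delta / r.sigma
        elif r.kind == "plane":
            pts = x[list(idx)]
            centroid = pts.mean(axis=0)
            centred = pts - centroid
            _, _, vt = np.linalg.svd(centred, full_matrices=False)
            normal = vt[-1]
            dists = centred @ normal
            value += w * float(np.sum(dists ** 2)) / r.sigma ** 2
            # the LS plane minimizes the sum, so only the explicit distance
            # dependence contributes to the gradient
            for a, di in zip(idx, dists):
                grad[a] += w * 2 * di / r.sigma ** 2 * normal
            res = float(np.sqrt(np.mean(dists ** 2))) / r.sigma
        elif r.kind == "chirality":
            i, j, k, l = idx
            v1 = x[j] - x[i]
            v2 = x[k] - x[i]
            v3 = x[l] - x[i]
            vol = float(np.dot(v1, np.cross(v2, v3)))
            ideal = target.chir_targets[id(r)]
            if r.sign == "both":
                ideal = abs(ideal) * (1.0 if vol >= 0 else -1.0)
            delta = vol - ideal
            value += w * (delta / CHIR_SIGMA) ** 2
            c = w * 2 * delta / CHIR_SIGMA ** 2
            g1 = np.cross(v2, v3)
            g2 = np.cross(v3, v1)
            g3 = np.cross(v1, v2)
            grad[j] += c * g1
            grad[k] += c * g2
            grad[l] += c * g3
            grad[i] -= c * (g1 + g2 + g3)
            res = delta / CHIR_SIGMA
        else:  # pragma: no cover
            continue
        if per_kind is not None:
            per_kind.setdefault(r.kind, []).append((r, res))
    if target.repulsion:
        n = len(x)
        for i in range(n):
            for j in range(i + 1, n):
                if frozenset((i, j)) in target.excluded_pairs:
                    continue
                r0 = target.repulsion_scale * (
                    covalent_radius(target.elements[i])
                    + covalent_radius(target.elements[j])
                )
                d = x[i] - x[j]
                dist = float(np.linalg.norm(d))
                if dist >= r0 or dist < 1e-12:
                    continue
                value += target.repulsion_weight * (r0 - dist) ** 4
                g = -target.repulsion_weight * 4 * (r0 - dist) ** 3 * d / dist
                grad[i] += g
                grad[j] -= g
    return value, grad


def rms_deviations(target: GeometryTarget, coords: np.ndarray) -> dict:
    """Per-kind RMS sigma-weighted deviations (RMSZ), overall and for
    link-provenance restraints separately."""
    per_kind: dict = {}
    evaluate(target, coords, per_kind=per_kind)
    out = {}
    for kind, entries in per_kind.items():
        z = np.array([res for _, res in entries])
        out[kind] = float(np.sqrt(np.mean(z ** 2)))
        link = np.array([res for r, res in entries
                         if r.provenance_class() == "link"])
        if link.size:
            out[f"{kind}/link"] = float(np.sqrt(np.mean(link ** 2)))
    return out


@dataclass
class MinimizeResult:
    coords: np.ndarray
    trajectory: list[float]
    rms_before: dict
    rms_after: dict
    cycles_done: int


def minimize(target: GeometryTarget, coords: np.ndarray | None = None,
             cycles: int = 20) -> MinimizeResult:
    """L-BFGS descent restricted to the moving mask; one cycle = one
    accepted (Armijo) step, so the value trajectory is non-increasing."""
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    x = (coords if coords is not None else target.coords()).astype(float).copy()
    mask = target.moving_mask[:, None]
    rms_before = rms_deviations(target, x)
    f, g = evaluate(target, x)
    g = g * mask
    traj = [f]
    mem: list[tuple[np.ndarray, np.ndarray]] = []
    m = 8
    done = 0
    for _ in range(cycles):
        q = g.ravel().copy()
        alphas = []
        for s, yv in reversed(mem):
            rho = 1.0 / float(yv.ravel() @ s.ravel())
            a = rho * float(s.ravel() @ q)
            alphas.append((a, rho, s, yv))
            q -= a * yv.ravel()
        if mem:
            s_last, y_last = mem[-1]
            gamma = float(s_last.ravel() @ y_last.ravel()) / float(
                y_last.ravel() @ y_last.ravel())
            q *= max(gamma, 1e-8)
        else:
            gn = np.linalg.norm(q)
            if gn > 0:
                q *= min(1.0, 0.3 / gn) / 1.0
        for a, rho, s, yv in reversed(alphas):
            b = rho * float(yv.ravel() @ q)
            q += (a - b) * s.ravel()
        p = -q.reshape(x.shape) * mask
        slope = float((g * p).sum())
        if slope >= 0 or not np.isfinite(slope):
            p = -g
            slope = float((g * p).sum())
            if slope >= 0:
                break
        alpha = 1.0
        accepted = False
        for _ls in range(40):
            xn = x + alpha * p
            fn, gn_ = evaluate(target, xn)
            if np.isfinite(fn) and fn <= f + 1e-4 * alpha * slope:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        gn_ = gn_ * mask
        s = (xn - x)
        yv = (gn_ - g)
        if float(s.ravel() @ yv.ravel()) > 1e-12:
            mem.append((s, yv))
            if len(mem) > m:
                mem.pop(0)
        x, f, g = xn, fn, gn_
        traj.append(f)
        done += 1
        if np.linalg.norm(g) < 1e-10:
            break
    rms_after = rms_deviations(target, x)
    return MinimizeResult(coords=x, trajectory=traj, rms_before=rms_before,
                          rms_after=rms_after, cycles_done=done)
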
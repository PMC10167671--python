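"""Riding-hydrogen placement from dictionary ideals.

Each hydrogen is placed exactly at its ideal bond distance from the parent
atom (electron-cloud or internuclear distance, selectable), with angles as
close as possible to their ideals in a least-squares sense, honoring
torsion, chirality and planarity templates.  Sites with multiple positions
that satisfy every condition (e.g. a free hydroxyl) or with an unknown
protonation state receive one deterministic canonical position with
occupancy zero, so that refinement-style consumers can ignore them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._geom import chiral_volume, normalize, place_atom
from .config import Options
from .errors import ModelError
from .linkage import LinkMatch, ResidueContext, resolve_model
from .model_io import AtomSite, StructureModel
from .monomer_library import MonomerLibrary, RestraintTemplate
from dataclasses import replace

from .restraints import RestraintSet, effective_definitions

logger = logging.getLogger("restraintsmith.hydrogens")

TETRAHEDRAL = 109.47


@dataclass
class HPlacementProblem:
    """Geometry available for positioning the hydrogens of one parent atom."""

    parent_name: str
    parent_pos: np.ndarray
    h_name: str
    distance: float
    known_neighbors: list[tuple[str, np.ndarray]]
    angle_constraints: list[tuple[np.ndarray, float, float]] = field(
        default_factory=list)      # (other-atom position, ideal, sigma)
    torsion: tuple[np.ndarray, np.ndarray, float, float] | None = None
    # (B position, A position, angle H-parent-B, torsion ideal) for H-parent-B-A
    chirality: tuple[np.ndarray, np.ndarray, str] | None = None
    plane: tuple[list[np.ndarray], float] | None = None
    canonical_ref: tuple[np.ndarray, np.ndarray] | None = None  # (B, A)
    prefer_sign: float = 0.0       # +1/-1 mirror-slot hint for CH2-type pairs


def classify_site(problem: HPlacementProblem) -> str:
    n = len(problem.known_neighbors)
    if n == 0:
        return "unsolvable"
    if n >= 3:
        return "three_neighbors"
    if n == 2:
        return "two_neighbors"
    if problem.torsion is not None:
        return "one_neighbor_with_torsion"
    return "one_neighbor_free"


def _ls_objective(problem: HPlacementProblem):
    p = problem.parent_pos
    d = problem.distance

    def f(x):
        th, ph = x
        u = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                      np.cos(th)])
        pos = p + d * u
        total = 0.0
        for other, ideal, sigma in problem.angle_constraints:
            v1 = pos - p
            v2 = other - p
            ang = np.degrees(np.arctan2(np.linalg.norm(np.cross(v1, v2)),
                                        np.dot(v1, v2)))
            total += ((ang - ideal) / sigma) ** 2
        if problem.plane is not None:
            members, sigma = problem.plane
            pts = np.array(members + [pos])
            centred = pts - pts.mean(axis=0)
            # distance of H to the least-squares plane of the site
            _, _, vt = np.linalg.svd(centred, full_matrices=False)
            normal = vt[-1]
            total += (float(np.dot(pos - pts.mean(axis=0), normal)) / sigma) ** 2
        return total

    return f


def _minimize_direction(problem: HPlacementProblem,
                        start: np.ndarray) -> tuple[np.ndarray, float]:
    f = _ls_objective(problem)
    th = float(np.arccos(np.clip(start[2], -1, 1)))
    ph = float(np.arctan2(start[1], start[0]))
    res = minimize(f, np.array([th, ph]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    th, ph = res.x
    u = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    return problem.parent_pos + problem.distance * u, float(res.fun)


def solve_problem(problem: HPlacementProblem) -> tuple[np.ndarray | None, bool]:
    """Returns (position, ambiguous); position None when unsolvable."""
    case = classify_site(problem)
    p = problem.parent_pos
    if case == "unsolvable":
        return None, False
    if case in ("one_neighbor_with_torsion",):
        bpos, apos, angle, tor = problem.torsion
        return place_atom(apos, bpos, p, problem.distance, angle, tor), False
    if case == "one_neighbor_free":
        if problem.canonical_ref is None:
            return None, False
        bpos, apos = problem.canonical_ref
        angle = problem.angle_constraints[0][1] if problem.angle_constraints \
            else TETRAHEDRAL
        return place_atom(apos, bpos, p, problem.distance, angle, 180.0), True
    # two or more neighbors: least squares on the sphere, started from the
    # frame-completing directions (mirror pair for the two-neighbor case)
    dirs = [normalize(pos - p) for _, pos in problem.known_neighbors]
    mean = -np.sum(dirs, axis=0)
    nm = np.linalg.norm(mean)
    mean = mean / nm if nm > 1e-8 else np.array([0.0, 0.0, 1.0])
    starts = [mean]
    if len(dirs) == 2:
        axis = np.cross(dirs[0], dirs[1])
        na = np.linalg.norm(axis)
        if na > 1e-8:
            axis = axis / na
            starts = [normalize(mean + axis), normalize(mean - axis)]
    solutions = []
    for s in starts:
        pos, fval = _minimize_direction(problem, s)
        solutions.append((fval, pos))
    solutions.sort(key=lambda t: t[0])
    if len(solutions) == 2:
        (f1, pos1), (f2, pos2) = solutions
        distinct = np.linalg.norm(pos1 - pos2) > 1e-4
        if distinct and abs(f1 - f2) < 1e-6:
            # mirror-symmetric pair: decide by chirality template if present,
            # otherwise by the requested mirror slot
            n1, n2 = (problem.known_neighbors[0][1],
                      problem.known_neighbors[1][1])
            if problem.chirality is not None:
                c1, c2, sign = problem.chirality
                want = 1.0 if sign == "positive" else -1.0
                for _, pos in solutions:
                    if np.sign(chiral_volume(p, c1, c2, pos)) == want:
                        return pos, False
                return solutions[0][1], False
            if problem.prefer_sign:
                for _, pos in solutions:
                    if (np.sign(chiral_volume(p, n1, n2, pos))
                            == problem.prefer_sign):
                        return pos, False
            return solutions[0][1], False
    return solutions[0][1], False


def nucleus_cloud_switch(rset: RestraintSet, mode: str) -> RestraintSet:
    """Select which of the two stored H bond ideals a restraint set uses.

    ``ideal`` always stores the electron-cloud distance as read from the
    dictionary; mode ``nucleus`` substitutes ``ideal_nucleus`` where present
    (warning where absent), mode ``electron_cloud`` returns the stored values.
    """
    if mode not in ("electron_cloud", "nucleus"):
        raise ValueError(f"unknown distance mode {mode!r}")
    out = RestraintSet()
    for r in rset:
        if r.kind == "bond" and mode == "nucleus":
            if r.ideal_nucleus is not None:
                out.add(replace(r, ideal=r.ideal_nucleus))
                continue
            if any(a.site is not None and a.site.element.upper() in ("H", "D")
                   for a in r.atoms):
                logger.warning(
                    "bond %s has no nucleus ideal; using the electron-cloud "
                    "value", tuple(a.name for a in r.atoms),
                )
        out.add(replace(r))
    return out


def _template_ideal(t: RestraintTemplate, mode: str) -> float:
    if mode == "nucleus" and t.ideal_nucleus is not None:
        return t.ideal_nucleus
    return t.ideal


def place_hydrogens(model: StructureModel, lib: MonomerLibrary,
                    matches: list[LinkMatch],
                    distance_mode: str = "electron_cloud",
                    regenerate: bool = True,
                    contexts: dict[int, ResidueContext] | None = None,
                    effective: dict | None = None) -> list[dict]:
    """Add riding hydrogens to the model in place; returns a report with one
    entry per attempted site."""
    if distance_mode not in ("electron_cloud", "nucleus"):
        raise ValueError(f"unknown distance mode {distance_mode!r}")
    contexts = contexts if contexts is not None else resolve_model(model, lib)
    effective = effective if effective is not None else effective_definitions(
        model, lib, matches, contexts)
    report: list[dict] = []

    if regenerate:
        for chain in model.chains:
            for res in chain.residues:
                res.atoms = [a for a in res.atoms
                             if a.element.upper() not in ("H", "D")]

    # link templates that may constrain hydrogens across residues
    external: list[tuple[RestraintTemplate, LinkMatch]] = []
    for m in matches:
        if m.link is not None:
            for t in m.link.templates:
                external.append((t, m))

    placed: dict[tuple[int, str, str], np.ndarray] = {}

    def local_atom_pos(ctx: ResidueContext, name: str, conf: str):
        hits = ctx.residue.find_atoms(name, conf or None)
        for a in hits:
            if a.altloc in ("", conf):
                return a.position
        std = ctx.std_name(name)
        for sib_hits in (ctx.find_atoms(std, conf or None),):
            for a in sib_hits:
                return a.position
        for key in ((id(ctx.residue), name, conf), (id(ctx.residue), name, "")):
            if key in placed:
                return placed[key]
        return None

    for chain in model.chains:
        for res in chain.residues:
            ctx = contexts[id(res)]
            confs = sorted({a.altloc for a in res.atoms if a.altloc}) or [""]
            for conf in confs:
                d = effective[(id(res), conf)]
                for spec in d.atoms:
                    if not spec.is_hydrogen:
                        continue
                    h = spec.name
                    altloc_for_h = conf if len(confs) > 1 else ""
                    if res.get_atom(h, conf or None) is not None:
                        continue  # kept existing hydrogen
                    if (id(res), h, altloc_for_h) in placed:
                        continue
                    heavies = [n for n in d.bonded_to(h)
                               if not d.get_atom(n).is_hydrogen]
                    if not heavies:
                        report.append(_entry(ctx, res, h, conf, "unsolvable",
                                             False))
                        continue
                    parent_name = heavies[0]
                    parent_atom = res.get_atom(parent_name, conf or None)
                    parent_pos = local_atom_pos(ctx, parent_name, conf)
                    if parent_pos is None:
                        report.append(_entry(ctx, res, h, conf, "unsolvable",
                                             False))
                        continue
                    problem = _build_problem(
                        ctx, res, conf, d, h, parent_name, parent_pos,
                        distance_mode, local_atom_pos, external,
                    )
                    pos, ambiguous = solve_problem(problem)
                    case = classify_site(problem)
                    if pos is None:
                        logger.warning(
                            "cannot place hydrogen %s of %s %s%d%s",
                            h, res.comp_id, ctx.chain_id, res.seq_id, res.icode,
                        )
                        report.append(_entry(ctx, res, h, conf, case, False))
                        continue
                    if h in d.ambiguous_h:
                        ambiguous = True
                    occ = 0.0 if ambiguous else (
                        parent_atom.occupancy if parent_atom else 1.0)
                    site = AtomSite(
                        name=h, element=spec.element, position=pos,
                        occupancy=occ, altloc=altloc_for_h,
                        b_iso=parent_atom.b_iso if parent_atom else 20.0,
                        is_generated_h=True,
                    )
                    res.atoms.append(site)
                    placed[(id(res), h, altloc_for_h)] = pos
                    entry = _entry(ctx, res, h, conf, case, ambiguous)
                    report.append(entry)
    return report


def _entry(ctx, res, h, conf, case, ambiguous) -> dict:
    return {"chain": ctx.chain_id, "seq_id": res.seq_id, "comp_id": res.comp_id,
            "atom": h, "altloc": conf, "case": case, "ambiguous": ambiguous}


def _build_problem(ctx, res, conf, d, h, parent_name, parent_pos,
                   distance_mode, local_atom_pos, external) -> HPlacementProblem:
    bond_t = d.bond_between(parent_name, h)
    if bond_t is None or bond_t.ideal is None:
        raise ModelError(f"no bond template for hydrogen {h} of {d.comp_id}")
    dist = _template_ideal(bond_t, distance_mode)
    problem = HPlacementProblem(
        parent_name=parent_name, parent_pos=parent_pos, h_name=h,
        distance=dist, known_neighbors=[],
    )
    for n in d.bonded_to(parent_name):
        if n == h:
            continue
        pos = local_atom_pos(ctx, n, conf)
        if pos is not None:
            problem.known_neighbors.append((n, pos))
    # sibling hydrogens on the same parent that are still to be placed get a
    # deterministic mirror slot: first pending sibling +, second -
    pending = [s.name for s in d.atoms
               if s.is_hydrogen and parent_name in d.bonded_to(s.name)
               and local_atom_pos(ctx, s.name, conf) is None]
    if h in pending and len(pending) >= 2:
        problem.prefer_sign = 1.0 if pending.index(h) == 0 else -1.0

    def add_templates(templates, resolver):
        for t in templates:
            if t.kind == "angle" and h in t.atom_names:
                names = t.atom_names
                if names[1] != parent_name:
                    continue
                if names[0] == h:
                    other = names[2]
                elif names[2] == h:
                    other = names[0]
                else:
                    continue
                pos = resolver(t, other)
                if pos is not None:
                    problem.angle_constraints.append((pos, t.ideal, t.sigma))
            elif t.kind == "torsion" and h in (t.atom_names[0], t.atom_names[3]):
                names = t.atom_names if t.atom_names[0] == h \
                    else tuple(reversed(t.atom_names))
                if names[1] != parent_name:
                    continue
                bpos = resolver(t, names[2])
                apos = resolver(t, names[3])
                if bpos is None or apos is None:
                    continue
                ang = TETRAHEDRAL
                for t2 in d.templates_of("angle"):
                    key = {t2.atom_names[0], t2.atom_names[2]}
                    if t2.atom_names[1] == parent_name and key == {h, names[2]}:
                        ang = t2.ideal
                problem.torsion = (bpos, apos, ang, t.ideal)
            elif t.kind == "chirality" and t.atom_names[0] == parent_name \
                    and h in t.atom_names[1:]:
                others = [n for n in t.atom_names[1:] if n != h]
                p1 = resolver(t, others[0])
                p2 = resolver(t, others[1])
                if p1 is not None and p2 is not None:
                    idx = list(t.atom_names[1:]).index(h)
                    sign = t.sign
                    # moving H out of third position flips parity per swap
                    swaps = 2 - idx
                    if swaps % 2 == 1 and sign in ("positive", "negative"):
                        sign = "negative" if sign == "positive" else "positive"
                    problem.chirality = (p1, p2, sign)
            elif t.kind == "plane" and h in t.atom_names:
                members = []
                for n in t.atom_names:
                    if n == h:
                        continue
                    pos = resolver(t, n)
                    if pos is not None:
                        members.append(pos)
                if len(members) >= 3:
                    problem.plane = (members, t.sigma)

    def _local(t, name):
        return local_atom_pos(ctx, name, conf)

    add_templates(d.templates, _local)

    # cross-residue link templates (e.g. the amide H angle and plane);
    # a cross-link bond makes the partner atom a known neighbor of the parent
    for t, m in external:
        if t.kind == "bond" and t.atom_sides and len(set(t.atom_sides)) == 2:
            for i, (name, side) in enumerate(zip(t.atom_names, t.atom_sides)):
                side_ctx = m.side1_ctx if side == 1 else m.side2_ctx
                if side_ctx.residue is not res:
                    continue
                if side_ctx.local_name(name) != parent_name:
                    continue
                oi = 1 - i
                o_side = t.atom_sides[oi]
                o_ctx = m.side1_ctx if o_side == 1 else m.side2_ctx
                o_alt = m.side1_altloc if o_side == 1 else m.side2_altloc
                pos = local_atom_pos(o_ctx, o_ctx.local_name(t.atom_names[oi]),
                                     o_alt or conf)
                if pos is not None and not any(
                    np.allclose(pos, kp) for _, kp in problem.known_neighbors
                ):
                    problem.known_neighbors.append(
                        (f"{o_ctx.residue.comp_id}:{t.atom_names[oi]}", pos))
        h_side = None
        for name, side in zip(t.atom_names, t.atom_sides):
            side_ctx = m.side1_ctx if side == 1 else m.side2_ctx
            if side_ctx.residue is res and side_ctx.local_name(name) == h:
                h_side = side
        if h_side is None:
            continue

        # rebuild a local-view template whose names match this residue's
        mapped_names = []
        for name, side in zip(t.atom_names, t.atom_sides):
            side_ctx = m.side1_ctx if side == 1 else m.side2_ctx
            mapped_names.append(
                side_ctx.local_name(name) if side_ctx.residue is res else name
            )
        t_local = replace(t, atom_names=tuple(mapped_names))

        def _ext_resolver(t2, name, _m=m, _t=t, _mapped=tuple(mapped_names)):
            idx = list(_mapped).index(name) if name in _mapped else None
            if idx is None:
                return None
            side = _t.atom_sides[idx]
            side_ctx = _m.side1_ctx if side == 1 else _m.side2_ctx
            alt = _m.side1_altloc if side == 1 else _m.side2_altloc
            return local_atom_pos(side_ctx,
                                  side_ctx.local_name(_t.atom_names[idx]),
                                  alt or conf)

        add_templates([t_local], _ext_resolver)

    # canonical reference for rotationally free sites: the lowest-named
    # non-parent neighbor of the parent's (single) heavy neighbor
    if len(problem.known_neighbors) == 1 and problem.torsion is None:
        bname, bpos = problem.known_neighbors[0]
        cands = sorted(n for n in d.bonded_to(bname)
                       if n != parent_name
                       and local_atom_pos(ctx, n, conf) is not None)
        if cands:
            problem.canonical_ref = (bpos, local_atom_pos(ctx, cands[0], conf))
    return problem
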
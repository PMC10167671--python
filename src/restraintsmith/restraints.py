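"""Restraint instantiation: from dictionary templates to concrete atoms.

For every residue the monomer templates are instantiated against the atoms
actually present; for every identified link the prescribed modifications
are applied to working copies of the two monomer definitions (possibly per
conformer — partial cleavage keeps the unlinked conformer's terminal atoms)
and the link's cross-templates are instantiated with alias-resolved names.
Bonds with no link description contribute a single fallback bond restraint
from covalent radii.  Duplicates keep the most specific provenance
(mod > link > monomer > fallback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from . import _cif
from .config import Options, covalent_radius
from .errors import ModelError
from .linkage import LinkMatch, ResidueContext, resolve_model
from .model_io import AtomSite, StructureModel
from .monomer_library import (
    MonomerDefinition,
    MonomerLibrary,
    apply_alias,
    apply_inverse_alias,
    apply_mod,
    canonical_atom_order,
)

logger = logging.getLogger("restraintsmith.restraints")

_PROVENANCE_RANK = {"mod": 3, "link": 2, "monomer": 1, "fallback": 0}


@dataclass
class AtomRef:
    """A restraint's pointer to one concrete model atom."""

    chain: str
    seq_id: int
    icode: str
    comp_id: str
    name: str
    altloc: str
    site: AtomSite | None = None

    def key(self) -> tuple:
        return (self.chain, self.seq_id, self.icode, self.comp_id, self.name,
                self.altloc)


@dataclass
class Restraint:
    kind: str
    atoms: tuple[AtomRef, ...]
    ideal: float | None
    sigma: float
    period: int = 1
    sign: str | None = None
    ideal_nucleus: float | None = None
    provenance: str = "monomer"
    zero_occ_h: bool = False

    def provenance_class(self) -> str:
        return self.provenance.split(":", 1)[0]

    def dedup_key(self) -> tuple:
        return (self.kind,
                canonical_atom_order(self.kind, tuple(a.key() for a in self.atoms)))


@dataclass
class RestraintSet:
    restraints: list[Restraint] = field(default_factory=list)

    def __iter__(self):
        return iter(self.restraints)

    def __len__(self):
        return len(self.restraints)

    def of_kind(self, kind: str) -> list[Restraint]:
        return [r for r in self.restraints if r.kind == kind]

    def add(self, r: Restraint) -> None:
        self.restraints.append(r)

    def deduplicate(self) -> None:
        """Keep one restraint per (kind, canonical atom tuple); the most
        specific provenance wins, later arrivals win ties."""
        best: dict[tuple, Restraint] = {}
        order: list[tuple] = []
        for r in self.restraints:
            k = r.dedup_key()
            if k not in best:
                best[k] = r
                order.append(k)
            else:
                old = best[k]
                if (_PROVENANCE_RANK[r.provenance_class()]
                        >= _PROVENANCE_RANK[old.provenance_class()]):
                    best[k] = r
        self.restraints = [best[k] for k in order]

    def comparable(self) -> set[tuple]:
        """Order-free content signature used in tests and censuses."""
        out = set()
        for r in self.restraints:
            out.add((
                r.kind,
                canonical_atom_order(r.kind, tuple(a.key() for a in r.atoms)),
                None if r.ideal is None else round(r.ideal, 6),
                round(r.sigma, 6), r.period, r.sign, r.provenance,
            ))
        return out


def _conformers(residue) -> list[str]:
    alts = sorted({a.altloc for a in residue.atoms if a.altloc})
    return alts if alts else [""]


def _pick_atom(hits: list[AtomSite], conf: str) -> AtomSite | None:
    if not hits:
        return None
    for a in hits:
        if a.altloc == conf:
            return a
    for a in hits:
        if a.altloc == "":
            return a
    return hits[0]


def _ref(ctx: ResidueContext, atom: AtomSite) -> AtomRef:
    res = ctx.residue
    if not any(a is atom for a in res.atoms):
        for sib in ctx.siblings:
            if any(a is atom for a in sib.residue.atoms):
                res = sib.residue
                break
    return AtomRef(ctx.chain_id, res.seq_id, res.icode, res.comp_id,
                   atom.name, atom.altloc, atom)


def effective_definitions(
    model: StructureModel, lib: MonomerLibrary, matches: list[LinkMatch],
    contexts: dict[int, ResidueContext] | None = None,
) -> dict[tuple[int, str], MonomerDefinition]:
    """Per-(residue, conformer) working definitions with link modifications
    applied.  Modifications triggered by a link apply to the conformer that
    participates in it; a blank-altloc participation applies to every
    conformer of the residue."""
    contexts = contexts if contexts is not None else resolve_model(model, lib)
    # collect mods per (residue, conformer)
    todo: dict[tuple[int, str], list[str]] = {}
    for m in matches:
        if m.link is None:
            continue
        for side, ctx, alt in ((m.link.side1, m.side1_ctx, m.side1_altloc),
                               (m.link.side2, m.side2_ctx, m.side2_altloc)):
            if side.mod_id is None:
                continue
            confs = [alt] if alt else _conformers(ctx.residue)
            for c in confs:
                todo.setdefault((id(ctx.residue), c), []).append(side.mod_id)
    out: dict[tuple[int, str], MonomerDefinition] = {}
    for chain in model.chains:
        for res in chain.residues:
            ctx = contexts[id(res)]
            for conf in _conformers(res):
                d = ctx.definition
                mods = sorted(set(todo.get((id(res), conf), [])))
                if mods:
                    work = apply_alias(d) if d.alias else d
                    for mod_id in mods:
                        work = apply_mod(work, lib.mod(mod_id))
                    if d.alias:
                        work = apply_inverse_alias(work)
                    d = work
                out[(id(res), conf)] = d
    return out


def build_restraints(model: StructureModel, lib: MonomerLibrary,
                     matches: list[LinkMatch],
                     options: Options | None = None,
                     contexts: dict[int, ResidueContext] | None = None,
                     effective: dict | None = None) -> RestraintSet:
    options = options or Options()
    contexts = contexts if contexts is not None else resolve_model(model, lib)
    effective = effective if effective is not None else effective_definitions(
        model, lib, matches, contexts)
    rset = RestraintSet()

    # monomer templates per residue, per conformer
    for chain in model.chains:
        for res in chain.residues:
            ctx = contexts[id(res)]
            for conf in _conformers(res):
                d = effective[(id(res), conf)]
                for t in d.templates:
                    atoms = []
                    for name in t.atom_names:
                        hits = ctx.find_atoms(ctx.std_name(name), conf or None)
                        a = _pick_atom(hits, conf)
                        if a is None:
                            atoms = None
                            break
                        atoms.append(a)
                    if atoms is None:
                        if t.kind == "plane":
                            # planes tolerate absent members if >=4 remain
                            atoms = []
                            for name in t.atom_names:
                                hits = ctx.find_atoms(ctx.std_name(name),
                                                      conf or None)
                                a = _pick_atom(hits, conf)
                                if a is not None:
                                    atoms.append(a)
                            if len(atoms) < 4:
                                logger.debug("plane %s of %s skipped", t.label,
                                             d.comp_id)
                                continue
                        else:
                            logger.debug("%s template %s of %s skipped (atom "
                                         "absent)", t.kind, t.atom_names,
                                         d.comp_id)
                            continue
                    rset.add(Restraint(
                        kind=t.kind,
                        atoms=tuple(_ref(ctx, a) for a in atoms),
                        ideal=t.ideal, sigma=t.sigma, period=t.period,
                        sign=t.sign, ideal_nucleus=t.ideal_nucleus,
                        provenance=t.provenance or f"monomer:{d.comp_id}",
                    ))

    # link cross-templates and fallbacks
    for m in matches:
        if m.link is None:
            a1, a2 = m.candidate.atoms(m.altlocs)
            ideal = covalent_radius(a1.element) + covalent_radius(a2.element)
            rset.add(Restraint(
                kind="bond",
                atoms=(_ref(m.candidate.ctx1, a1), _ref(m.candidate.ctx2, a2)),
                ideal=round(ideal, 3), sigma=options.fallback_bond_sigma,
                provenance="fallback",
            ))
            continue
        for t in m.link.templates:
            atoms = []
            for name, side in zip(t.atom_names, t.atom_sides):
                ctx = m.side1_ctx if side == 1 else m.side2_ctx
                alt = m.side1_altloc if side == 1 else m.side2_altloc
                hits = ctx.find_atoms(name, alt or None)
                a = _pick_atom(hits, alt)
                if a is None:
                    atoms.append(None)
                else:
                    atoms.append((ctx, a))
            if any(a is None for a in atoms):
                if t.kind == "plane":
                    atoms = [a for a in atoms if a is not None]
                    if len(atoms) < 4:
                        logger.warning("link %s plane template skipped (too "
                                       "few atoms present)", m.link.link_id)
                        continue
                else:
                    missing = [n for n, a in zip(t.atom_names, atoms)
                               if a is None]
                    logger.warning(
                        "link %s %s template skipped: atom(s) %s absent",
                        m.link.link_id, t.kind, ",".join(missing),
                    )
                    continue
            rset.add(Restraint(
                kind=t.kind,
                atoms=tuple(_ref(ctx, a) for ctx, a in atoms),
                ideal=t.ideal, sigma=t.sigma, period=t.period, sign=t.sign,
                ideal_nucleus=t.ideal_nucleus,
                provenance=f"link:{m.link.link_id}",
            ))

    for r in rset:
        r.zero_occ_h = any(
            a.site is not None and a.site.is_generated_h
            and a.site.occupancy == 0.0 for a in r.atoms
        )
    rset.deduplicate()
    _check_no_dangling(rset, model)
    return rset


def _check_no_dangling(rset: RestraintSet, model: StructureModel) -> None:
    sites = {id(a) for _, _, a in model.all_atoms()}
    for r in rset:
        for a in r.atoms:
            if a.site is None or id(a.site) not in sites:
                raise ModelError(
                    f"restraint {r.kind} references atom {a.key()} that is "
                    f"not in the model"
                )


def restraint_census(rset: RestraintSet) -> dict:
    """Counts by kind and provenance class, in stable sorted order."""
    by_kind: dict[str, int] = {}
    by_prov: dict[str, int] = {}
    by_kind_prov: dict[str, int] = {}
    for r in rset:
        pc = r.provenance_class()
        by_kind[r.kind] = by_kind.get(r.kind, 0) + 1
        by_prov[pc] = by_prov.get(pc, 0) + 1
        key = f"{r.kind}/{pc}"
        by_kind_prov[key] = by_kind_prov.get(key, 0) + 1
    return {
        "total": len(rset),
        "by_kind": dict(sorted(by_kind.items())),
        "by_provenance": dict(sorted(by_prov.items())),
        "by_kind_provenance": dict(sorted(by_kind_prov.items())),
    }


# --- restraint file ----------------------------------------------------------

_ATOM_COLS = ("chain", "seq", "icode", "comp", "atom", "alt")


def _atom_cells(a: AtomRef) -> list:
    return [a.chain, a.seq_id, a.icode or None, a.comp_id, a.name,
            a.altloc or None]


def write_restraint_file(rset: RestraintSet, model: StructureModel) -> str:
    """Deterministic CIF-style serialization; one category per restraint
    kind, atoms addressed by chain/seq/icode/comp/atom/altloc.  This format
    is this package's own documented dialect."""
    out = ["data_restraints"]

    def cols(prefix: str, natoms: int, extra: tuple[str, ...]) -> list[str]:
        names = []
        for i in range(1, natoms + 1):
            names += [f"_{prefix}.{c}_{i}" for c in _ATOM_COLS]
        names += [f"_{prefix}.{c}" for c in extra]
        return names

    def fnum(v):
        return None if v is None else f"{v:g}"

    bonds = [r for r in rset.of_kind("bond")]
    _cif.write_loop(
        out, cols("restr_bond", 2, ("ideal", "sigma", "ideal_nucleus",
                                    "zero_occ_h", "provenance")),
        [[*_atom_cells(r.atoms[0]), *_atom_cells(r.atoms[1]),
          fnum(r.ideal), fnum(r.sigma), fnum(r.ideal_nucleus),
          "y" if r.zero_occ_h else "n", r.provenance] for r in bonds],
    )
    _cif.write_loop(
        out, cols("restr_angle", 3, ("ideal", "sigma", "zero_occ_h",
                                     "provenance")),
        [[*(c for a in r.atoms for c in _atom_cells(a)),
          fnum(r.ideal), fnum(r.sigma), "y" if r.zero_occ_h else "n",
          r.provenance] for r in rset.of_kind("angle")],
    )
    _cif.write_loop(
        out, cols("restr_torsion", 4, ("ideal", "sigma", "period",
                                       "zero_occ_h", "provenance")),
        [[*(c for a in r.atoms for c in _atom_cells(a)),
          fnum(r.ideal), fnum(r.sigma), r.period,
          "y" if r.zero_occ_h else "n", r.provenance]
         for r in rset.of_kind("torsion")],
    )
    _cif.write_loop(
        out, cols("restr_chir", 4, ("sign", "sigma", "zero_occ_h",
                                    "provenance")),
        [[*(c for a in r.atoms for c in _atom_cells(a)),
          r.sign, fnum(r.sigma), "y" if r.zero_occ_h else "n", r.provenance]
         for r in rset.of_kind("chirality")],
    )
    plane_rows = []
    for i, r in enumerate(rset.of_kind("plane")):
        for a in r.atoms:
            plane_rows.append([f"plane{i + 1}", *_atom_cells(a),
                               fnum(r.sigma),
                               "y" if r.zero_occ_h else "n", r.provenance])
    _cif.write_loop(
        out,
        ["_restr_plane.id"] + [f"_restr_plane.{c}_1" for c in _ATOM_COLS]
        + ["_restr_plane.sigma", "_restr_plane.zero_occ_h",
           "_restr_plane.provenance"],
        plane_rows,
    )
    return "\n".join(out) + "\n"


def read_restraint_file(text: str, model: StructureModel) -> RestraintSet:
    """Parse the dialect written by :func:`write_restraint_file`, resolving
    atoms back against the model."""
    blocks = _cif.parse(text)
    rset = RestraintSet()

    def ref(row: dict, i: int) -> AtomRef:
        chain = row[f"chain_{i}"]
        seq = int(row[f"seq_{i}"])
        icode = row.get(f"icode_{i}") or ""
        comp = row[f"comp_{i}"]
        name = row[f"atom_{i}"]
        alt = row.get(f"alt_{i}") or ""
        site = None
        for r in model.find_residues(chain, seq, icode, comp):
            for a in r.atoms:
                if a.name == name and a.altloc == alt:
                    site = a
                    break
        if site is None:
            raise ModelError(
                f"restraint file references missing atom {chain}/{seq}{icode}/"
                f"{comp}/{name}/{alt or '.'}"
            )
        return AtomRef(chain, seq, icode, comp, name, alt, site)

    def num(row, key):
        v = row.get(key)
        return None if v is None else float(v)

    for row in _cif.category_rows(blocks, "_restr_bond"):
        rset.add(Restraint("bond", (ref(row, 1), ref(row, 2)),
                           num(row, "ideal"), num(row, "sigma"),
                           ideal_nucleus=num(row, "ideal_nucleus"),
                           zero_occ_h=row.get("zero_occ_h") == "y",
                           provenance=row["provenance"]))
    for row in _cif.category_rows(blocks, "_restr_angle"):
        rset.add(Restraint("angle", tuple(ref(row, i) for i in (1, 2, 3)),
                           num(row, "ideal"), num(row, "sigma"),
                           zero_occ_h=row.get("zero_occ_h") == "y",
                           provenance=row["provenance"]))
    for row in _cif.category_rows(blocks, "_restr_torsion"):
        rset.add(Restraint("torsion", tuple(ref(row, i) for i in (1, 2, 3, 4)),
                           num(row, "ideal"), num(row, "sigma"),
                           period=int(row.get("period") or 1),
                           zero_occ_h=row.get("zero_occ_h") == "y",
                           provenance=row["provenance"]))
    for row in _cif.category_rows(blocks, "_restr_chir"):
        rset.add(Restraint("chirality", tuple(ref(row, i) for i in (1, 2, 3, 4)),
                           None, num(row, "sigma"), sign=row.get("sign"),
                           zero_occ_h=row.get("zero_occ_h") == "y",
                           provenance=row["provenance"]))
    planes: dict[str, list[dict]] = {}
    for row in _cif.category_rows(blocks, "_restr_plane"):
        planes.setdefault(row["id"], []).append(row)
    for rows in planes.values():
        rset.add(Restraint(
            "plane", tuple(ref(row, 1) for row in rows), None,
            float(rows[0]["sigma"]),
            zero_occ_h=rows[0].get("zero_occ_h") == "y",
            provenance=rows[0]["provenance"],
        ))
    return rset
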
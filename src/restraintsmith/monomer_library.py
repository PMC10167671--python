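"""Monomer-library dictionaries: monomers, links, modifications, aliases.

A monomer description (``chem_comp``) holds the atoms of one chemical
building block together with ideal values and standard uncertainties for
bonds, angles, torsions, planes and chiral centres.  Links (``chem_link``)
describe covalent bonds between two monomers — selected either by specific
component id or by chemical *group* — and prescribe modifications
(``chem_mod``) to the bonded monomers, e.g. deletion of the leaving OXT
atom when a peptide bond forms.  An optional alias table
(``_chem_comp_alias``) maps nonstandard atom names onto the standard names
that a group's links expect, so that standard link descriptions apply to
monomers with noncanonical nomenclature.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from . import _cif
from .errors import ModApplicationError, SchemaError

logger = logging.getLogger("restraintsmith.monomer_library")

GAP_LINK_ID = "gap"


class ChemGroup(str, Enum):
    """Chemical group taxonomy used by generic link selectors."""

    PEPTIDE = "peptide"
    P_PEPTIDE = "P-peptide"
    M_PEPTIDE = "M-peptide"
    DNA = "DNA"
    RNA = "RNA"
    PYRANOSE = "pyranose"
    KETOPYRANOSE = "ketopyranose"
    FURANOSE = "furanose"
    NON_POLYMER = "non-polymer"


_PEPTIDE_CLASS = {ChemGroup.PEPTIDE, ChemGroup.P_PEPTIDE, ChemGroup.M_PEPTIDE}
_NA_CLASS = {ChemGroup.DNA, ChemGroup.RNA}


def groups_compatible(a: ChemGroup, b: ChemGroup) -> bool:
    """Link-side compatibility: reflexive; the three peptide-class groups are
    mutually compatible, as are DNA and RNA; everything else must match exactly."""
    if a == b:
        return True
    if a in _PEPTIDE_CLASS and b in _PEPTIDE_CLASS:
        return True
    if a in _NA_CLASS and b in _NA_CLASS:
        return True
    return False


def parse_group(s: str) -> ChemGroup:
    norm = s.strip().replace("_", "-")
    for g in ChemGroup:
        if g.value.lower() == norm.lower():
            return g
    raise SchemaError(f"unknown chemical group {s!r}")


@dataclass
class AtomSpec:
    name: str
    element: str
    chemical_type: str = ""
    charge: float = 0.0
    is_leaving: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


RESTRAINT_KINDS = ("bond", "angle", "torsion", "plane", "chirality")
CHIR_SIGNS = ("positive", "negative", "both")


@dataclass
class RestraintTemplate:
    """One ideal-geometry record: 2 atoms for a bond, 3 for an angle, 4 for a
    torsion or a chiral centre (centre first), >=4 for a plane.

    Bonds to hydrogen may carry two ideals: the electron-cloud centre distance
    (``ideal``) and the internuclear distance (``ideal_nucleus``).  For planes
    ``sigma`` is the per-atom deviation sigma and ``ideal`` is unused.
    ``atom_sides`` is set only on link templates and tags each atom name with
    the link side (1 or 2) it belongs to.
    """

    kind: str
    atom_names: tuple[str, ...]
    ideal: float | None = None
    sigma: float = 0.02
    period: int = 1
    ideal_nucleus: float | None = None
    sign: str | None = None
    atom_sides: tuple[int, ...] | None = None
    label: str | None = None
    provenance: str | None = None

    def validate(self) -> None:
        k = self.kind
        n = len(self.atom_names)
        if k not in RESTRAINT_KINDS:
            raise SchemaError(f"unknown restraint kind {k!r}")
        expect = {"bond": 2, "angle": 3, "torsion": 4, "chirality": 4}
        if k == "plane":
            if n < 4:
                raise SchemaError(f"plane {self.label!r} needs >=4 atoms, got {n}")
        elif n != expect[k]:
            raise SchemaError(f"{k} template needs {expect[k]} atoms, got {n}")
        if k in ("bond", "angle", "torsion", "plane") and not self.sigma > 0:
            raise SchemaError(f"{k} template sigma must be positive: {self.sigma}")
        if k == "angle" and not (0 < self.ideal < 180):
            raise SchemaError(f"angle ideal out of (0, 180): {self.ideal}")
        if k == "torsion":
            if not (-180 < self.ideal <= 180):
                raise SchemaError(f"torsion ideal out of (-180, 180]: {self.ideal}")
            if self.period < 1:
                raise SchemaError(f"torsion period must be >=1: {self.period}")
        if k == "chirality" and self.sign not in CHIR_SIGNS:
            raise SchemaError(f"chirality sign must be one of {CHIR_SIGNS}: {self.sign}")
        if self.ideal_nucleus is not None and k != "bond":
            raise SchemaError("only bonds may carry a nucleus ideal")

    def rename(self, mapping: dict[str, str]) -> "RestraintTemplate":
        return replace(
            self, atom_names=tuple(mapping.get(a, a) for a in self.atom_names)
        )


def canonical_atom_order(kind: str, atoms: tuple) -> tuple:
    """Canonical ordering used for duplicate detection.

    Bonds/angles/torsions are direction-symmetric and compared against their
    reversal; planes are order-free; chiral centres are never reordered.
    """
    if kind in ("bond", "angle", "torsion"):
        rev = tuple(reversed(atoms))
        return min(atoms, rev)
    if kind == "plane":
        return tuple(sorted(atoms))
    return tuple(atoms)


@dataclass
class AliasTable:
    """Bijective map from a monomer's own atom names to the standard names of
    its group, enabling standard link descriptions on nonstandard nomenclature."""

    group_context: ChemGroup
    pairs: dict[str, str]  # name in monomer -> standard name

    def validate(self) -> None:
        if len(set(self.pairs.values())) != len(self.pairs):
            raise SchemaError("alias table is not injective on standard names")

    def to_standard(self, name: str) -> str:
        return self.pairs.get(name, name)

    def from_standard(self, name: str) -> str:
        inv = self.inverse_pairs()
        return inv.get(name, name)

    def inverse_pairs(self) -> dict[str, str]:
        return {v: k for k, v in self.pairs.items()}

    def inverted(self) -> "AliasTable":
        return AliasTable(self.group_context, self.inverse_pairs())


@dataclass
class MonomerDefinition:
    comp_id: str
    group: ChemGroup
    atoms: list[AtomSpec] = field(default_factory=list)
    templates: list[RestraintTemplate] = field(default_factory=list)
    alias: AliasTable | None = None
    # hydrogens whose protonation state is unknown (placed at occupancy zero)
    ambiguous_h: set[str] = field(default_factory=set)
    # set by apply_alias so that original names can be restored on output
    applied_alias: AliasTable | None = None

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}

    def get_atom(self, name: str) -> AtomSpec | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def templates_of(self, kind: str) -> list[RestraintTemplate]:
        return [t for t in self.templates if t.kind == kind]

    def bond_between(self, a: str, b: str) -> RestraintTemplate | None:
        key = canonical_atom_order("bond", (a, b))
        for t in self.templates:
            if t.kind == "bond" and canonical_atom_order("bond", t.atom_names) == key:
                return t
        return None

    def bonded_to(self, name: str) -> list[str]:
        out = []
        for t in self.templates_of("bond"):
            if t.atom_names[0] == name:
                out.append(t.atom_names[1])
            elif t.atom_names[1] == name:
                out.append(t.atom_names[0])
        return out

    def copy(self) -> "MonomerDefinition":
        return _copy.deepcopy(self)

    def validate(self) -> None:
        names = [a.name for a in self.atoms]
        seen = set()
        for n in names:
            if not n:
                raise SchemaError(f"{self.comp_id}: empty atom name")
            if n in seen:
                raise SchemaError(f"{self.comp_id}: duplicate atom name {n!r}")
            seen.add(n)
        bond_keys = set()
        for t in self.templates:
            t.validate()
            for a in t.atom_names:
                if a not in seen:
                    raise SchemaError(
                        f"{self.comp_id}: {t.kind} template references unknown atom {a!r}"
                    )
            if t.kind == "bond":
                key = canonical_atom_order("bond", t.atom_names)
                if key in bond_keys:
                    raise SchemaError(
                        f"{self.comp_id}: more than one bond template for pair {key}"
                    )
                bond_keys.add(key)
        if self.alias is not None:
            self.alias.validate()
            for name in self.alias.pairs:
                if name not in seen:
                    raise SchemaError(
                        f"{self.comp_id}: alias source atom {name!r} not in monomer"
                    )
            # a standard target must not collide with an existing, unaliased name
            for src, tgt in self.alias.pairs.items():
                if tgt in seen and tgt not in self.alias.pairs:
                    raise SchemaError(
                        f"{self.comp_id}: alias target {tgt!r} collides with an "
                        f"existing atom name"
                    )


@dataclass
class ChemModAction:
    """One edit step of a modification.

    ``verb`` is one of add_atom / delete_atom / change_atom / add_restraint /
    delete_restraint / change_restraint.  Exactly the payload fields relevant
    to the verb are set.
    """

    verb: str
    atom: AtomSpec | None = None          # add_atom
    name: str | None = None               # delete_atom / change_atom
    changes: dict | None = None           # change_atom / change_restraint
    template: RestraintTemplate | None = None  # add_restraint
    kind: str | None = None               # delete_restraint / change_restraint
    atom_names: tuple[str, ...] | None = None  # delete_restraint / change_restraint


@dataclass
class ChemMod:
    mod_id: str
    actions: list[ChemModAction] = field(default_factory=list)


@dataclass
class LinkSide:
    """Selector for one side of a link: either a specific component id or a
    chemical group (a side with neither is a wildcard, used only by ``gap``)."""

    comp_id: str | None = None
    group: ChemGroup | None = None
    mod_id: str | None = None

    def validate(self, link_id: str) -> None:
        if self.comp_id is not None and self.group is not None:
            raise SchemaError(
                f"link {link_id}: side has both comp_id and group selectors set"
            )


@dataclass
class LinkDefinition:
    link_id: str
    side1: LinkSide
    side2: LinkSide
    templates: list[RestraintTemplate] = field(default_factory=list)

    def cross_bonds(self) -> list[RestraintTemplate]:
        return [
            t
            for t in self.templates
            if t.kind == "bond" and t.atom_sides and len(set(t.atom_sides)) == 2
        ]

    def validate(self) -> None:
        self.side1.validate(self.link_id)
        self.side2.validate(self.link_id)
        for t in self.templates:
            t.validate()
            if t.atom_sides is None or len(t.atom_sides) != len(t.atom_names):
                raise SchemaError(
                    f"link {self.link_id}: template missing side tags"
                )
            if any(s not in (1, 2) for s in t.atom_sides):
                raise SchemaError(f"link {self.link_id}: side tags must be 1 or 2")
        ncross = len(self.cross_bonds())
        if self.link_id == GAP_LINK_ID:
            if self.templates:
                raise SchemaError("the gap link must not carry restraint templates")
        elif ncross != 1:
            raise SchemaError(
                f"link {self.link_id}: expected exactly one cross-link bond, "
                f"found {ncross}"
            )


# --- parsing -----------------------------------------------------------------

_KNOWN_TAGS = {
    "_chem_comp": {"id", "three_letter_code", "name", "group", "number_atoms_all",
                   "number_atoms_nh", "desc_level", "ambiguous_protonation_atoms"},
    "_chem_comp_atom": {"comp_id", "atom_id", "type_symbol", "type_energy",
                        "charge", "partial_charge", "leaving_atom",
                        "pdbx_leaving_atom_flag", "x", "y", "z"},
    "_chem_comp_bond": {"comp_id", "atom_id_1", "atom_id_2", "type",
                        "aromatic", "value_dist", "value_dist_esd",
                        "value_dist_nucleus", "value_dist_nucleus_esd"},
    "_chem_comp_angle": {"comp_id", "atom_id_1", "atom_id_2", "atom_id_3",
                         "value_angle", "value_angle_esd"},
    "_chem_comp_tor": {"comp_id", "id", "atom_id_1", "atom_id_2", "atom_id_3",
                       "atom_id_4", "value_angle", "value_angle_esd", "period"},
    "_chem_comp_chir": {"comp_id", "id", "atom_id_centre", "atom_id_1",
                        "atom_id_2", "atom_id_3", "volume_sign"},
    "_chem_comp_plane_atom": {"comp_id", "plane_id", "atom_id", "dist_esd"},
    "_chem_comp_alias": {"comp_id", "group", "atom_id", "atom_id_standard"},
}


def _warn_unknown_tags(blocks: list[_cif.Block], known: dict[str, set[str]]) -> None:
    for block in blocks:
        tags = list(block.items)
        for loop in block.loops:
            tags.extend(loop.tags)
        for t in tags:
            cat, _, item = t.partition(".")
            if cat in known and item not in known[cat]:
                logger.warning("ignoring unknown dictionary tag %s", t)


def _f(row: dict, key: str, context: str) -> float | None:
    v = row.get(key)
    if v is None:
        return None
    try:
        return float(v)
    except ValueError as e:
        raise SchemaError(f"{context}: bad number {v!r} for {key}") from e


def _req(row: dict, key: str, context: str) -> str:
    v = row.get(key)
    if v is None:
        raise SchemaError(f"{context}: missing required item {key}")
    return v


def parse_monomers(text: str) -> list[MonomerDefinition]:
    """Parse every chem_comp description in a CIF document."""
    blocks = _cif.parse(text)
    _warn_unknown_tags(blocks, _KNOWN_TAGS)
    groups: dict[str, ChemGroup] = {}
    ambis: dict[str, set[str]] = {}
    for row in _cif.category_rows(blocks, "_chem_comp"):
        cid = row.get("id")
        if cid and row.get("group"):
            groups[cid] = parse_group(row["group"])
        if cid and row.get("ambiguous_protonation_atoms"):
            ambis[cid] = set(row["ambiguous_protonation_atoms"].split())

    per_comp: dict[str, MonomerDefinition] = {}

    def get_def(comp_id: str) -> MonomerDefinition:
        if comp_id not in per_comp:
            per_comp[comp_id] = MonomerDefinition(
                comp_id=comp_id,
                group=groups.get(comp_id, ChemGroup.NON_POLYMER),
                ambiguous_h=ambis.get(comp_id, set()),
            )
        return per_comp[comp_id]

    for row in _cif.category_rows(blocks, "_chem_comp_atom"):
        cid = _req(row, "comp_id", "_chem_comp_atom")
        leaving = (row.get("leaving_atom") or row.get("pdbx_leaving_atom_flag") or "n")
        get_def(cid).atoms.append(
            AtomSpec(
                name=_req(row, "atom_id", "_chem_comp_atom"),
                element=_req(row, "type_symbol", "_chem_comp_atom"),
                chemical_type=row.get("type_energy") or "",
                charge=_f(row, "charge", "_chem_comp_atom") or 0.0,
                is_leaving=leaving.lower() in ("y", "yes"),
            )
        )
    for row in _cif.category_rows(blocks, "_chem_comp_bond"):
        cid = _req(row, "comp_id", "_chem_comp_bond")
        get_def(cid).templates.append(
            RestraintTemplate(
                kind="bond",
                atom_names=(row["atom_id_1"], row["atom_id_2"]),
                ideal=_f(row, "value_dist", cid),
                sigma=_f(row, "value_dist_esd", cid) or 0.02,
                ideal_nucleus=_f(row, "value_dist_nucleus", cid),
            )
        )
    for row in _cif.category_rows(blocks, "_chem_comp_angle"):
        cid = _req(row, "comp_id", "_chem_comp_angle")
        get_def(cid).templates.append(
            RestraintTemplate(
                kind="angle",
                atom_names=(row["atom_id_1"], row["atom_id_2"], row["atom_id_3"]),
                ideal=_f(row, "value_angle", cid),
                sigma=_f(row, "value_angle_esd", cid) or 2.0,
            )
        )
    for row in _cif.category_rows(blocks, "_chem_comp_tor"):
        cid = _req(row, "comp_id", "_chem_comp_tor")
        get_def(cid).templates.append(
            RestraintTemplate(
                kind="torsion",
                atom_names=(row["atom_id_1"], row["atom_id_2"],
                            row["atom_id_3"], row["atom_id_4"]),
                ideal=_f(row, "value_angle", cid),
                sigma=_f(row, "value_angle_esd", cid) or 10.0,
                period=int(row.get("period") or 1),
                label=row.get("id"),
            )
        )
    for row in _cif.category_rows(blocks, "_chem_comp_chir"):
        cid = _req(row, "comp_id", "_chem_comp_chir")
        sign = (row.get("volume_sign") or "").lower()
        get_def(cid).templates.append(
            RestraintTemplate(
                kind="chirality",
                atom_names=(row["atom_id_centre"], row["atom_id_1"],
                            row["atom_id_2"], row["atom_id_3"]),
                sign=sign,
                sigma=0.2,
                label=row.get("id"),
            )
        )
    # plane atoms arrive one row per atom; group them by (comp, plane_id)
    planes: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for row in _cif.category_rows(blocks, "_chem_comp_plane_atom"):
        cid = _req(row, "comp_id", "_chem_comp_plane_atom")
        pid = row.get("plane_id") or "plan-1"
        planes.setdefault((cid, pid), []).append(
            (row["atom_id"], _f(row, "dist_esd", cid) or 0.02)
        )
    for (cid, pid), members in planes.items():
        get_def(cid).templates.append(
            RestraintTemplate(
                kind="plane",
                atom_names=tuple(a for a, _ in members),
                sigma=members[0][1],
                label=pid,
            )
        )
    alias_rows: dict[str, list[dict]] = {}
    for row in _cif.category_rows(blocks, "_chem_comp_alias"):
        cid = _req(row, "comp_id", "_chem_comp_alias")
        alias_rows.setdefault(cid, []).append(row)
    for cid, rows in alias_rows.items():
        pairs: dict[str, str] = {}
        for row in rows:
            src = _req(row, "atom_id", "_chem_comp_alias")
            tgt = _req(row, "atom_id_standard", "_chem_comp_alias")
            if src in pairs:
                raise SchemaError(f"{cid}: duplicate alias source {src!r}")
            pairs[src] = tgt
        gctx = rows[0].get("group")
        get_def(cid).alias = AliasTable(
            group_context=parse_group(gctx) if gctx else get_def(cid).group,
            pairs=pairs,
        )

    out = list(per_comp.values())
    for d in out:
        if not d.atoms:
            raise SchemaError(f"{d.comp_id}: chem_comp block has no atoms")
        d.validate()
    return out


def parse_monomer_cif(text: str) -> MonomerDefinition:
    """Parse a document containing a single chem_comp description."""
    defs = parse_monomers(text)
    if not defs:
        raise SchemaError("no chem_comp description found in document")
    if len(defs) > 1:
        logger.warning("document defines %d monomers; returning the first", len(defs))
    return defs[0]


_LINK_KNOWN = {
    "_chem_link": {"id", "name", "comp_id_1", "mod_id_1", "group_comp_1",
                   "comp_id_2", "mod_id_2", "group_comp_2"},
}


def _side(row: dict, n: int, link_id: str) -> LinkSide:
    comp = row.get(f"comp_id_{n}") or None
    grp = row.get(f"group_comp_{n}") or None
    side = LinkSide(
        comp_id=comp,
        group=parse_group(grp) if grp else None,
        mod_id=row.get(f"mod_id_{n}") or None,
    )
    side.validate(link_id)
    return side


def parse_link_cif(text: str) -> list[LinkDefinition]:
    """Parse every chem_link description in a CIF document."""
    blocks = _cif.parse(text)
    links: dict[str, LinkDefinition] = {}
    for row in _cif.category_rows(blocks, "_chem_link"):
        lid = _req(row, "id", "_chem_link")
        links[lid] = LinkDefinition(
            link_id=lid, side1=_side(row, 1, lid), side2=_side(row, 2, lid)
        )

    def link_of(row: dict, cat: str) -> LinkDefinition:
        lid = _req(row, "link_id", cat)
        if lid not in links:
            raise SchemaError(f"{cat}: restraint row for undeclared link {lid!r}")
        return links[lid]

    def sides_names(row: dict, count: int, cat: str):
        names, sides = [], []
        for i in range(1, count + 1):
            names.append(_req(row, f"atom_id_{i}", cat))
            sides.append(int(_req(row, f"atom_{i}_comp_id", cat)))
        return tuple(names), tuple(sides)

    for row in _cif.category_rows(blocks, "_chem_link_bond"):
        names, sides = sides_names(row, 2, "_chem_link_bond")
        link_of(row, "_chem_link_bond").templates.append(
            RestraintTemplate(
                kind="bond", atom_names=names, atom_sides=sides,
                ideal=_f(row, "value_dist", "_chem_link_bond"),
                sigma=_f(row, "value_dist_esd", "_chem_link_bond") or 0.02,
                ideal_nucleus=_f(row, "value_dist_nucleus", "_chem_link_bond"),
            )
        )
    for row in _cif.category_rows(blocks, "_chem_link_angle"):
        names, sides = sides_names(row, 3, "_chem_link_angle")
        link_of(row, "_chem_link_angle").templates.append(
            RestraintTemplate(
                kind="angle", atom_names=names, atom_sides=sides,
                ideal=_f(row, "value_angle", "_chem_link_angle"),
                sigma=_f(row, "value_angle_esd", "_chem_link_angle") or 2.0,
            )
        )
    for row in _cif.category_rows(blocks, "_chem_link_tor"):
        names, sides = sides_names(row, 4, "_chem_link_tor")
        link_of(row, "_chem_link_tor").templates.append(
            RestraintTemplate(
                kind="torsion", atom_names=names, atom_sides=sides,
                ideal=_f(row, "value_angle", "_chem_link_tor"),
                sigma=_f(row, "value_angle_esd", "_chem_link_tor") or 10.0,
                period=int(row.get("period") or 1),
                label=row.get("id"),
            )
        )
    for row in _cif.category_rows(blocks, "_chem_link_chir"):
        names = (
            _req(row, "atom_id_centre", "_chem_link_chir"),
            row["atom_id_1"], row["atom_id_2"], row["atom_id_3"],
        )
        sides = (
            int(_req(row, "atom_centre_comp_id", "_chem_link_chir")),
            int(row["atom_1_comp_id"]), int(row["atom_2_comp_id"]),
            int(row["atom_3_comp_id"]),
        )
        link_of(row, "_chem_link_chir").templates.append(
            RestraintTemplate(
                kind="chirality", atom_names=names, atom_sides=sides,
                sign=(row.get("volume_sign") or "").lower(), sigma=0.2,
                label=row.get("id"),
            )
        )
    lplanes: dict[tuple[str, str], list[tuple[str, int, float]]] = {}
    for row in _cif.category_rows(blocks, "_chem_link_plane"):
        lid = _req(row, "link_id", "_chem_link_plane")
        pid = row.get("plane_id") or "plan-1"
        lplanes.setdefault((lid, pid), []).append(
            (row["atom_id"], int(row["atom_comp_id"]),
             _f(row, "dist_esd", "_chem_link_plane") or 0.02)
        )
    for (lid, pid), members in lplanes.items():
        if lid not in links:
            raise SchemaError(f"_chem_link_plane: rows for undeclared link {lid!r}")
        links[lid].templates.append(
            RestraintTemplate(
                kind="plane",
                atom_names=tuple(a for a, _, _ in members),
                atom_sides=tuple(s for _, s, _ in members),
                sigma=members[0][2],
                label=pid,
            )
        )
    out = sorted(links.values(), key=lambda l: l.link_id)
    for l in out:
        l.validate()
    return out


def parse_mod_cif(text: str) -> list[ChemMod]:
    """Parse every chem_mod description in a CIF document."""
    blocks = _cif.parse(text)
    mods: dict[str, ChemMod] = {}
    for row in _cif.category_rows(blocks, "_chem_mod"):
        mid = _req(row, "id", "_chem_mod")
        mods[mid] = ChemMod(mod_id=mid)

    def mod_of(row: dict, cat: str) -> ChemMod:
        mid = _req(row, "mod_id", cat)
        if mid not in mods:
            raise SchemaError(f"{cat}: action row for undeclared mod {mid!r}")
        return mods[mid]

    for row in _cif.category_rows(blocks, "_chem_mod_atom"):
        fn = (_req(row, "function", "_chem_mod_atom")).lower()
        name = _req(row, "atom_id", "_chem_mod_atom")
        if fn == "add":
            action = ChemModAction(
                verb="add_atom",
                atom=AtomSpec(
                    name=name,
                    element=_req(row, "new_type_symbol", "_chem_mod_atom"),
                    chemical_type=row.get("new_type_energy") or "",
                    charge=_f(row, "new_charge", "_chem_mod_atom") or 0.0,
                ),
            )
        elif fn == "delete":
            action = ChemModAction(verb="delete_atom", name=name)
        elif fn == "change":
            changes = {}
            if row.get("new_type_symbol"):
                changes["element"] = row["new_type_symbol"]
            if row.get("new_type_energy"):
                changes["chemical_type"] = row["new_type_energy"]
            if row.get("new_charge") is not None:
                changes["charge"] = float(row["new_charge"])
            action = ChemModAction(verb="change_atom", name=name, changes=changes)
        else:
            raise SchemaError(f"_chem_mod_atom: unknown function {fn!r}")
        mod_of(row, "_chem_mod_atom").actions.append(action)

    def restraint_rows(cat: str, kind: str, natoms: int, value_key: str,
                       esd_key: str, extra=None):
        for row in _cif.category_rows(blocks, cat):
            fn = (_req(row, "function", cat)).lower()
            names = tuple(_req(row, f"atom_id_{i}", cat) for i in range(1, natoms + 1))
            if fn == "delete":
                action = ChemModAction(verb="delete_restraint", kind=kind,
                                       atom_names=names)
            elif fn in ("add", "change"):
                changes = {}
                if row.get(value_key) is not None:
                    changes["ideal"] = float(row[value_key])
                if row.get(esd_key) is not None:
                    changes["sigma"] = float(row[esd_key])
                if extra:
                    changes.update(extra(row))
                if fn == "add":
                    action = ChemModAction(
                        verb="add_restraint",
                        template=RestraintTemplate(kind=kind, atom_names=names,
                                                   **changes),
                    )
                else:
                    action = ChemModAction(verb="change_restraint", kind=kind,
                                           atom_names=names, changes=changes)
            else:
                raise SchemaError(f"{cat}: unknown function {fn!r}")
            mod_of(row, cat).actions.append(action)

    restraint_rows(
        "_chem_mod_bond", "bond", 2, "new_value_dist", "new_value_dist_esd",
        extra=lambda r: (
            {"ideal_nucleus": float(r["new_value_dist_nucleus"])}
            if r.get("new_value_dist_nucleus") is not None else {}
        ),
    )
    restraint_rows("_chem_mod_angle", "angle", 3, "new_value_angle",
                   "new_value_angle_esd")
    restraint_rows(
        "_chem_mod_tor", "torsion", 4, "new_value_angle", "new_value_angle_esd",
        extra=lambda r: ({"period": int(r["period"])} if r.get("period") else {}),
    )
    return sorted(mods.values(), key=lambda m: m.mod_id)


# --- modification and alias application --------------------------------------


def apply_mod(base: MonomerDefinition, mod: ChemMod) -> MonomerDefinition:
    """Apply a modification, returning a new definition; ``base`` is unchanged.

    Actions apply strictly in listed order.  Deleting an atom cascades:
    every template referencing it is removed.  A change_restraint overrides
    only the fields it names.
    """
    d = base.copy()
    prov = f"mod:{mod.mod_id}"
    for action in mod.actions:
        v = action.verb
        if v == "add_atom":
            if d.get_atom(action.atom.name) is not None:
                raise ModApplicationError(
                    f"mod {mod.mod_id}: add_atom {action.atom.name!r} already exists "
                    f"in {d.comp_id}"
                )
            d.atoms.append(_copy.deepcopy(action.atom))
        elif v == "delete_atom":
            if d.get_atom(action.name) is None:
                raise ModApplicationError(
                    f"mod {mod.mod_id}: delete_atom {action.name!r} not found in "
                    f"{d.comp_id}"
                )
            d.atoms = [a for a in d.atoms if a.name != action.name]
            d.templates = [
                t for t in d.templates if action.name not in t.atom_names
            ]
        elif v == "change_atom":
            atom = d.get_atom(action.name)
            if atom is None:
                raise ModApplicationError(
                    f"mod {mod.mod_id}: change_atom {action.name!r} not found in "
                    f"{d.comp_id}"
                )
            for k, val in (action.changes or {}).items():
                setattr(atom, k, val)
        elif v == "add_restraint":
            t = _copy.deepcopy(action.template)
            t.provenance = prov
            d.templates.append(t)
        elif v in ("delete_restraint", "change_restraint"):
            key = canonical_atom_order(action.kind, action.atom_names)
            hits = [
                t for t in d.templates
                if t.kind == action.kind
                and canonical_atom_order(t.kind, t.atom_names) == key
            ]
            if not hits:
                raise ModApplicationError(
                    f"mod {mod.mod_id}: {v} found no {action.kind} restraint on "
                    f"{action.atom_names} in {d.comp_id}"
                )
            if v == "delete_restraint":
                d.templates = [t for t in d.templates if t not in hits]
            else:
                for t in hits:
                    for k, val in (action.changes or {}).items():
                        setattr(t, k, val)
                    t.provenance = prov
        else:
            raise ModApplicationError(f"mod {mod.mod_id}: unknown verb {v!r}")
    d.validate()
    return d


def apply_alias(d: MonomerDefinition) -> MonomerDefinition:
    """Rename atoms and template references to the standard names of the
    monomer's group; the table used is retained for the inverse mapping."""
    if d.alias is None:
        return d
    mapping = dict(d.alias.pairs)
    out = d.copy()
    for a in out.atoms:
        a.name = mapping.get(a.name, a.name)
    out.templates = [t.rename(mapping) for t in out.templates]
    out.applied_alias = d.alias
    out.alias = None
    out.validate()
    return out


def apply_inverse_alias(d: MonomerDefinition) -> MonomerDefinition:
    """Undo :func:`apply_alias` using the retained table."""
    if d.applied_alias is None:
        return d
    mapping = d.applied_alias.inverse_pairs()
    out = d.copy()
    for a in out.atoms:
        a.name = mapping.get(a.name, a.name)
    out.templates = [t.rename(mapping) for t in out.templates]
    # aliased atoms may have been deleted by a modification in the meantime;
    # keep only pairs whose source atom still exists
    names = {a.name for a in out.atoms}
    out.alias = AliasTable(
        d.applied_alias.group_context,
        {src: tgt for src, tgt in d.applied_alias.pairs.items() if src in names},
    )
    out.applied_alias = None
    out.validate()
    return out


# --- serialization -----------------------------------------------------------


def monomer_to_cif(d: MonomerDefinition) -> str:
    ambi = " ".join(sorted(d.ambiguous_h)) if d.ambiguous_h else None
    out: list[str] = [
        "data_comp_list",
        "loop_",
        "_chem_comp.id",
        "_chem_comp.group",
        "_chem_comp.ambiguous_protonation_atoms",
        f"{_cif.format_value(d.comp_id)} {_cif.format_value(d.group.value)} "
        f"{_cif.format_value(ambi)}",
        "",
        f"data_comp_{d.comp_id}",
    ]
    _cif.write_loop(
        out,
        [f"_chem_comp_atom.{k}" for k in
         ("comp_id", "atom_id", "type_symbol", "type_energy", "charge",
          "leaving_atom")],
        [[d.comp_id, a.name, a.element, a.chemical_type, a.charge,
          "y" if a.is_leaving else "n"] for a in d.atoms],
    )
    bonds = d.templates_of("bond")
    _cif.write_loop(
        out,
        [f"_chem_comp_bond.{k}" for k in
         ("comp_id", "atom_id_1", "atom_id_2", "value_dist", "value_dist_esd",
          "value_dist_nucleus")],
        [[d.comp_id, *t.atom_names, t.ideal, t.sigma, t.ideal_nucleus]
         for t in bonds],
    )
    _cif.write_loop(
        out,
        [f"_chem_comp_angle.{k}" for k in
         ("comp_id", "atom_id_1", "atom_id_2", "atom_id_3", "value_angle",
          "value_angle_esd")],
        [[d.comp_id, *t.atom_names, t.ideal, t.sigma]
         for t in d.templates_of("angle")],
    )
    _cif.write_loop(
        out,
        [f"_chem_comp_tor.{k}" for k in
         ("comp_id", "id", "atom_id_1", "atom_id_2", "atom_id_3", "atom_id_4",
          "value_angle", "value_angle_esd", "period")],
        [[d.comp_id, t.label or f"tor_{i + 1}", *t.atom_names, t.ideal, t.sigma,
          t.period] for i, t in enumerate(d.templates_of("torsion"))],
    )
    _cif.write_loop(
        out,
        [f"_chem_comp_chir.{k}" for k in
         ("comp_id", "id", "atom_id_centre", "atom_id_1", "atom_id_2",
          "atom_id_3", "volume_sign")],
        [[d.comp_id, t.label or f"chir_{i + 1}", *t.atom_names, t.sign]
         for i, t in enumerate(d.templates_of("chirality"))],
    )
    plane_rows = []
    for i, t in enumerate(d.templates_of("plane")):
        pid = t.label or f"plan-{i + 1}"
        for a in t.atom_names:
            plane_rows.append([d.comp_id, pid, a, t.sigma])
    _cif.write_loop(
        out,
        [f"_chem_comp_plane_atom.{k}" for k in
         ("comp_id", "plane_id", "atom_id", "dist_esd")],
        plane_rows,
    )
    if d.alias is not None:
        _cif.write_loop(
            out,
            [f"_chem_comp_alias.{k}" for k in
             ("comp_id", "group", "atom_id", "atom_id_standard")],
            [[d.comp_id, d.alias.group_context.value, src, tgt]
             for src, tgt in d.alias.pairs.items()],
        )
    return "\n".join(out) + "\n"


def links_to_cif(links: list[LinkDefinition]) -> str:
    out: list[str] = ["data_link_list"]
    _cif.write_loop(
        out,
        [f"_chem_link.{k}" for k in
         ("id", "comp_id_1", "mod_id_1", "group_comp_1", "comp_id_2",
          "mod_id_2", "group_comp_2")],
        [[l.link_id,
          l.side1.comp_id, l.side1.mod_id,
          l.side1.group.value if l.side1.group else None,
          l.side2.comp_id, l.side2.mod_id,
          l.side2.group.value if l.side2.group else None] for l in links],
    )
    for l in links:
        out.append("")
        out.append(f"data_link_{l.link_id}")
        _cif.write_loop(
            out,
            [f"_chem_link_bond.{k}" for k in
             ("link_id", "atom_1_comp_id", "atom_id_1", "atom_2_comp_id",
              "atom_id_2", "value_dist", "value_dist_esd", "value_dist_nucleus")],
            [[l.link_id, t.atom_sides[0], t.atom_names[0], t.atom_sides[1],
              t.atom_names[1], t.ideal, t.sigma, t.ideal_nucleus]
             for t in l.templates if t.kind == "bond"],
        )
        _cif.write_loop(
            out,
            [f"_chem_link_angle.{k}" for k in
             ("link_id", "atom_1_comp_id", "atom_id_1", "atom_2_comp_id",
              "atom_id_2", "atom_3_comp_id", "atom_id_3", "value_angle",
              "value_angle_esd")],
            [[l.link_id, t.atom_sides[0], t.atom_names[0], t.atom_sides[1],
              t.atom_names[1], t.atom_sides[2], t.atom_names[2], t.ideal,
              t.sigma] for t in l.templates if t.kind == "angle"],
        )
        _cif.write_loop(
            out,
            [f"_chem_link_tor.{k}" for k in
             ("link_id", "id", "atom_1_comp_id", "atom_id_1", "atom_2_comp_id",
              "atom_id_2", "atom_3_comp_id", "atom_id_3", "atom_4_comp_id",
              "atom_id_4", "value_angle", "value_angle_esd", "period")],
            [[l.link_id, t.label or "tor_1", t.atom_sides[0], t.atom_names[0],
              t.atom_sides[1], t.atom_names[1], t.atom_sides[2], t.atom_names[2],
              t.atom_sides[3], t.atom_names[3], t.ideal, t.sigma, t.period]
             for t in l.templates if t.kind == "torsion"],
        )
        _cif.write_loop(
            out,
            [f"_chem_link_chir.{k}" for k in
             ("link_id", "id", "atom_centre_comp_id", "atom_id_centre",
              "atom_1_comp_id", "atom_id_1", "atom_2_comp_id", "atom_id_2",
              "atom_3_comp_id", "atom_id_3", "volume_sign")],
            [[l.link_id, t.label or "chir_1", t.atom_sides[0], t.atom_names[0],
              t.atom_sides[1], t.atom_names[1], t.atom_sides[2], t.atom_names[2],
              t.atom_sides[3], t.atom_names[3], t.sign]
             for t in l.templates if t.kind == "chirality"],
        )
        plane_rows = []
        for i, t in enumerate(t2 for t2 in l.templates if t2.kind == "plane"):
            pid = t.label or f"plan-{i + 1}"
            for a, s in zip(t.atom_names, t.atom_sides):
                plane_rows.append([l.link_id, pid, s, a, t.sigma])
        _cif.write_loop(
            out,
            [f"_chem_link_plane.{k}" for k in
             ("link_id", "plane_id", "atom_comp_id", "atom_id", "dist_esd")],
            plane_rows,
        )
    return "\n".join(out) + "\n"


def mods_to_cif(mods: list[ChemMod]) -> str:
    out: list[str] = ["data_mod_list"]
    _cif.write_loop(out, ["_chem_mod.id"], [[m.mod_id] for m in mods])
    for m in mods:
        out.append("")
        out.append(f"data_mod_{m.mod_id}")
        atom_rows, bond_rows, angle_rows, tor_rows = [], [], [], []
        for a in m.actions:
            if a.verb == "add_atom":
                atom_rows.append([m.mod_id, "add", a.atom.name, a.atom.element,
                                  a.atom.chemical_type, a.atom.charge])
            elif a.verb == "delete_atom":
                atom_rows.append([m.mod_id, "delete", a.name, None, None, None])
            elif a.verb == "change_atom":
                ch = a.changes or {}
                atom_rows.append([m.mod_id, "change", a.name, ch.get("element"),
                                  ch.get("chemical_type"), ch.get("charge")])
            elif a.verb in ("add_restraint", "delete_restraint",
                            "change_restraint"):
                if a.verb == "add_restraint":
                    kind, names = a.template.kind, a.template.atom_names
                    ch = {"ideal": a.template.ideal, "sigma": a.template.sigma,
                          "ideal_nucleus": a.template.ideal_nucleus,
                          "period": a.template.period}
                    fn = "add"
                else:
                    kind, names = a.kind, a.atom_names
                    ch = dict(a.changes or {})
                    fn = "delete" if a.verb == "delete_restraint" else "change"
                if kind == "bond":
                    bond_rows.append([m.mod_id, fn, *names, ch.get("ideal"),
                                      ch.get("sigma"), ch.get("ideal_nucleus")])
                elif kind == "angle":
                    angle_rows.append([m.mod_id, fn, *names, ch.get("ideal"),
                                       ch.get("sigma")])
                elif kind == "torsion":
                    tor_rows.append([m.mod_id, fn, *names, ch.get("ideal"),
                                     ch.get("sigma"), ch.get("period")])
                else:
                    raise SchemaError(
                        f"mod {m.mod_id}: cannot serialize {kind} restraint action"
                    )
        _cif.write_loop(
            out,
            [f"_chem_mod_atom.{k}" for k in
             ("mod_id", "function", "atom_id", "new_type_symbol",
              "new_type_energy", "new_charge")],
            atom_rows,
        )
        _cif.write_loop(
            out,
            [f"_chem_mod_bond.{k}" for k in
             ("mod_id", "function", "atom_id_1", "atom_id_2", "new_value_dist",
              "new_value_dist_esd", "new_value_dist_nucleus")],
            bond_rows,
        )
        _cif.write_loop(
            out,
            [f"_chem_mod_angle.{k}" for k in
             ("mod_id", "function", "atom_id_1", "atom_id_2", "atom_id_3",
              "new_value_angle", "new_value_angle_esd")],
            angle_rows,
        )
        _cif.write_loop(
            out,
            [f"_chem_mod_tor.{k}" for k in
             ("mod_id", "function", "atom_id_1", "atom_id_2", "atom_id_3",
              "atom_id_4", "new_value_angle", "new_value_angle_esd", "period")],
            tor_rows,
        )
    return "\n".join(out) + "\n"


# --- library container -------------------------------------------------------


class MonomerLibrary:
    """A set of monomer, link and modification dictionaries.

    The on-disk layout is ``<root>/<first-letter-lowercased>/<COMP_ID>.cif``
    for monomers plus ``<root>/list/links.cif`` and ``<root>/list/mods.cif``.
    Additional files loaded later override earlier definitions with the same
    id (user dictionaries win over the base library).
    """

    def __init__(self) -> None:
        self.monomers: dict[str, MonomerDefinition] = {}
        self.links: dict[str, LinkDefinition] = {}
        self.mods: dict[str, ChemMod] = {}

    @classmethod
    def load(cls, root: str | Path,
             extra_files: list[str | Path] | None = None) -> "MonomerLibrary":
        lib = cls()
        root = Path(root)
        for path in sorted(root.glob("[a-z0-9]/*.cif")):
            lib.add_document(path.read_text())
        for name in ("links.cif", "mods.cif"):
            p = root / "list" / name
            if p.exists():
                lib.add_document(p.read_text())
        for f in extra_files or []:
            lib.add_document(Path(f).read_text())
        return lib

    @classmethod
    def from_files(cls, files: list[str | Path]) -> "MonomerLibrary":
        lib = cls()
        for f in files:
            lib.add_document(Path(f).read_text())
        return lib

    def add_document(self, text: str) -> None:
        blocks = _cif.parse(text)
        cats = _cif.categories_present(blocks)
        if any(c.startswith("_chem_comp") for c in cats):
            for d in parse_monomers(text):
                self.monomers[d.comp_id] = d
        if "_chem_link" in cats or any(c.startswith("_chem_link_") for c in cats):
            for l in parse_link_cif(text):
                self.links[l.link_id] = l
        if "_chem_mod" in cats or any(c.startswith("_chem_mod_") for c in cats):
            for m in parse_mod_cif(text):
                self.mods[m.mod_id] = m

    def monomer(self, comp_id: str) -> MonomerDefinition:
        try:
            return self.monomers[comp_id]
        except KeyError:
            raise SchemaError(
                f"monomer {comp_id!r} not found in the loaded library"
            ) from None

    def link(self, link_id: str) -> LinkDefinition:
        try:
            return self.links[link_id]
        except KeyError:
            from .errors import LinkIdentificationError
            known = ", ".join(sorted(self.links))
            raise LinkIdentificationError(
                f"link {link_id!r} not found; known links: {known}"
            ) from None

    def mod(self, mod_id: str) -> ChemMod:
        try:
            return self.mods[mod_id]
        except KeyError:
            raise SchemaError(
                f"modification {mod_id!r} not found in the loaded library"
            ) from None
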
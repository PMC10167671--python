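"""Covalent-link identification.

Decides which covalent bonds exist between residues of a model and which
link description applies to each.  Bonds between consecutive polymer
residues are implicit and accepted when the linking atoms (C->N for the
peptide groups, O3'->P for nucleic acids, after alias resolution) lie
within a per-polymer-type distance cutoff; explicit LINK records override
the distance check, a LINKR record named ``gap`` suppresses the implicit
bond, and a LINKR / ``_struct_conn.ccp4_link_id`` name binds the bond
directly to that link description.  Unnamed bonds are scored against every
loaded link description — an exact component match is more specific than a
group match — and ties of equal specificity (e.g. TRANS vs CIS) are broken
by comparing the link's torsion ideals and chirality signs with the model.
Bonds with no matching description fall back to a single bond-length
restraint derived from the chemical types of the two atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._geom import chiral_volume, periodic_delta, torsion_deg
from .config import Options, covalent_radius
from .errors import ModelError
from .monomer_library import (
    GAP_LINK_ID,
    ChemGroup,
    LinkDefinition,
    MonomerLibrary,
    MonomerDefinition,
    groups_compatible,
)
from .model_io import AtomSite, Residue, StructureModel

logger = logging.getLogger("restraintsmith.linkage")

_PEPTIDE_GROUPS = {ChemGroup.PEPTIDE, ChemGroup.P_PEPTIDE, ChemGroup.M_PEPTIDE}
_NA_GROUPS = {ChemGroup.DNA, ChemGroup.RNA}


@dataclass
class ResidueContext:
    """A residue resolved against the library."""

    chain_id: str
    residue: Residue
    definition: MonomerDefinition
    siblings: list[Residue] = field(default_factory=list)  # same position

    def local_name(self, std_name: str) -> str:
        """Translate a group-standard atom name to this monomer's own name."""
        if self.definition.alias is not None:
            return self.definition.alias.from_standard(std_name)
        return std_name

    def std_name(self, local_name: str) -> str:
        if self.definition.alias is not None:
            return self.definition.alias.to_standard(local_name)
        return local_name

    def find_atoms(self, std_name: str, altloc: str | None = None,
                   search_siblings: bool = True) -> list[AtomSite]:
        """Atoms by standard name, looking through shared-atom siblings
        (microheterogeneity) for blank-altloc atoms if not found locally."""
        hits = self.residue.find_atoms(self.local_name(std_name), altloc)
        if hits or not search_siblings:
            return hits
        for sib in self.siblings:
            for a in sib.find_atoms(std_name, altloc):
                if a.altloc == "":
                    hits.append(a)
        return hits


@dataclass
class BondCandidate:
    """A potential inter-residue covalent bond prior to link matching."""

    ctx1: ResidueContext
    ctx2: ResidueContext
    std_name1: str
    std_name2: str
    origin: str                         # implicit_polymer | conn_record | distance_search
    named_link_id: str | None = None
    altloc_pairing: list[tuple[str, str]] = field(default_factory=list)
    reported_distance: float | None = None

    def atoms(self, altlocs: tuple[str, str]) -> tuple[AtomSite, AtomSite]:
        a1 = self.ctx1.find_atoms(self.std_name1, altlocs[0] or None)
        a2 = self.ctx2.find_atoms(self.std_name2, altlocs[1] or None)
        if not a1 or not a2:
            raise ModelError(
                f"cannot resolve bond atoms {self.std_name1}/{self.std_name2}"
            )
        return a1[0], a2[0]


@dataclass
class LinkMatch:
    candidate: BondCandidate
    link: LinkDefinition | None         # None => bond-only fallback
    orientation: bool                   # True: ctx1 is side1
    specificity: int = 0
    exactness: int = 0                  # exact-group side count (tie rank)
    altlocs: tuple[str, str] = ("", "")
    fallback: bool = False

    @property
    def side1_ctx(self) -> ResidueContext:
        return self.candidate.ctx1 if self.orientation else self.candidate.ctx2

    @property
    def side2_ctx(self) -> ResidueContext:
        return self.candidate.ctx2 if self.orientation else self.candidate.ctx1

    @property
    def side1_altloc(self) -> str:
        return self.altlocs[0] if self.orientation else self.altlocs[1]

    @property
    def side2_altloc(self) -> str:
        return self.altlocs[1] if self.orientation else self.altlocs[0]


def resolve_model(model: StructureModel, lib: MonomerLibrary) -> dict[int, ResidueContext]:
    """Attach a library definition to every residue; returns contexts keyed
    by id(residue).  Missing monomers raise a schema error listing them."""
    missing = sorted({
        r.comp_id for _, r, _ in
        ((c, r, None) for c in model.chains for r in c.residues)
        if r.comp_id not in lib.monomers
    })
    if missing:
        from .errors import SchemaError
        raise SchemaError(
            "monomer(s) not found in the loaded library: " + ", ".join(missing)
        )
    contexts: dict[int, ResidueContext] = {}
    for chain in model.chains:
        for group in chain.positions():
            for r in group:
                contexts[id(r)] = ResidueContext(
                    chain_id=chain.chain_id,
                    residue=r,
                    definition=lib.monomer(r.comp_id),
                    siblings=[ResidueContext(chain.chain_id, s, lib.monomer(s.comp_id))
                              for s in group if s is not r],
                )
    return contexts


def _altloc_pairings(atoms1: list[AtomSite], atoms2: list[AtomSite],
                     cutoff: float | None) -> list[tuple[str, str]]:
    """Conformer pairings: altlocs pair when equal or when either is blank;
    a blank atom may participate in several pairings (shared atoms)."""
    pairs = []
    for a1 in atoms1:
        for a2 in atoms2:
            if a1.altloc and a2.altloc and a1.altloc != a2.altloc:
                continue
            if cutoff is not None:
                if float(np.linalg.norm(a1.position - a2.position)) > cutoff:
                    continue
            pairs.append((a1.altloc, a2.altloc))
    return sorted(set(pairs))


def _polymer_link_atoms(g1: ChemGroup, g2: ChemGroup) -> tuple[str, str] | None:
    if g1 in _PEPTIDE_GROUPS and g2 in _PEPTIDE_GROUPS:
        return ("C", "N")
    if g1 in _NA_GROUPS and g2 in _NA_GROUPS:
        return ("O3'", "P")
    return None


def _conn_covers(cr_atoms, cand: BondCandidate) -> bool:
    """Does a connectivity record address the same atom pair as an implicit
    polymer candidate?"""
    (r1a, n1), (r2a, n2) = cr_atoms
    c1 = (cand.ctx1.residue, cand.ctx1.local_name(cand.std_name1))
    c2 = (cand.ctx2.residue, cand.ctx2.local_name(cand.std_name2))
    fwd = (r1a is c1[0] and n1 == c1[1] and r2a is c2[0] and n2 == c2[1])
    rev = (r1a is c2[0] and n1 == c2[1] and r2a is c1[0] and n2 == c1[1])
    return fwd or rev


def find_bond_candidates(model: StructureModel, lib: MonomerLibrary,
                         options: Options | None = None,
                         contexts: dict[int, ResidueContext] | None = None,
                         ) -> list[BondCandidate]:
    options = options or Options()
    contexts = contexts if contexts is not None else resolve_model(model, lib)
    candidates: list[BondCandidate] = []

    # resolve connectivity records to residues once
    conn_resolved = []
    for cr in model.conn:
        res = []
        for addr in (cr.atom1, cr.atom2):
            hits = model.resolve(addr)
            if not hits:
                res = None
                break
            res.append(hits)
        if res is None:
            logger.warning(
                "dropping connectivity record %s: atoms not found in model",
                cr.kind,
            )
            continue
        conn_resolved.append((cr, res))

    covered_by_conn: set[int] = set()

    # implicit polymer candidates between consecutive positions
    for chain in model.chains:
        positions = chain.positions()
        for p1, p2 in zip(positions, positions[1:]):
            for r1 in p1:
                for r2 in p2:
                    ctx1, ctx2 = contexts[id(r1)], contexts[id(r2)]
                    names = _polymer_link_atoms(ctx1.definition.group,
                                                ctx2.definition.group)
                    if names is None:
                        continue
                    std1, std2 = names
                    cutoff = (options.peptide_cutoff()
                              if std1 == "C" else options.nucleic_cutoff())
                    atoms1 = ctx1.find_atoms(std1)
                    atoms2 = ctx2.find_atoms(std2)
                    if not atoms1 or not atoms2:
                        continue
                    cand = BondCandidate(ctx1, ctx2, std1, std2,
                                         origin="implicit_polymer")
                    # explicit records can force or suppress the implicit bond
                    gap = False
                    forced = False
                    named = None
                    for i, (cr, res) in enumerate(conn_resolved):
                        addrs = ((res[0][0][0], cr.atom1.atom),
                                 (res[1][0][0], cr.atom2.atom))
                        if not _conn_covers(addrs, cand):
                            continue
                        covered_by_conn.add(i)
                        if cr.named_link_id == GAP_LINK_ID:
                            gap = True
                        else:
                            forced = True
                            named = cr.named_link_id or named
                    if gap:
                        logger.info(
                            "gap record suppresses implicit bond %s%d-%s%d",
                            chain.chain_id, r1.seq_id, chain.chain_id, r2.seq_id,
                        )
                        continue
                    pairing = _altloc_pairings(
                        atoms1, atoms2, None if forced else cutoff
                    )
                    if not pairing:
                        continue
                    cand.altloc_pairing = pairing
                    cand.named_link_id = named
                    candidates.append(cand)

    # remaining connectivity records become candidates of their own
    for i, (cr, res) in enumerate(conn_resolved):
        if i in covered_by_conn:
            continue
        if cr.named_link_id == GAP_LINK_ID:
            logger.warning("gap record does not name an implicit polymer bond; "
                           "ignored")
            continue
        r1, a1 = res[0][0]
        r2, a2 = res[1][0]
        ctx1, ctx2 = contexts[id(r1)], contexts[id(r2)]
        cand = BondCandidate(
            ctx1, ctx2,
            ctx1.std_name(cr.atom1.atom), ctx2.std_name(cr.atom2.atom),
            origin="conn_record",
            named_link_id="SS" if cr.kind == "SSBOND" else cr.named_link_id,
            reported_distance=cr.reported_distance,
        )
        atoms1 = [a for _, a in res[0]]
        atoms2 = [a for _, a in res[1]]
        cand.altloc_pairing = _altloc_pairings(atoms1, atoms2, None)
        if cand.altloc_pairing:
            candidates.append(cand)

    if options.auto_links:
        candidates.extend(_distance_search(model, contexts, candidates, options))
    return candidates


def _distance_search(model, contexts, existing, options) -> list[BondCandidate]:
    """Optional automatic bond detection from interatomic distances."""
    covered = set()
    for cand in existing:
        key = frozenset((id(cand.ctx1.residue), id(cand.ctx2.residue)))
        covered.add(key)
    out = []
    residues = [(c, r) for c in model.chains for r in c.residues]
    for i, (c1, r1) in enumerate(residues):
        for c2, r2 in residues[i + 1:]:
            key = frozenset((id(r1), id(r2)))
            if key in covered:
                continue
            best = None
            for a1 in r1.atoms:
                if a1.element.upper() in ("H", "D"):
                    continue
                for a2 in r2.atoms:
                    if a2.element.upper() in ("H", "D"):
                        continue
                    if a1.altloc and a2.altloc and a1.altloc != a2.altloc:
                        continue
                    lim = (covalent_radius(a1.element) +
                           covalent_radius(a2.element) +
                           options.auto_link_tolerance)
                    d = float(np.linalg.norm(a1.position - a2.position))
                    if d <= lim and (best is None or d < best[0]):
                        best = (d, a1, a2)
            if best is None:
                continue
            _, a1, a2 = best
            ctx1, ctx2 = contexts[id(r1)], contexts[id(r2)]
            cand = BondCandidate(
                ctx1, ctx2, ctx1.std_name(a1.name), ctx2.std_name(a2.name),
                origin="distance_search",
            )
            cand.altloc_pairing = [(a1.altloc, a2.altloc)]
            out.append(cand)
            covered.add(key)
    return out


# --- specificity scoring -----------------------------------------------------


def _side_score(side, comp_id: str, group: ChemGroup,
                alias_group: ChemGroup | None) -> tuple[int, int] | None:
    """Exact component match scores 2, a group match (native or via the
    alias table's declared group) scores 1, otherwise no match.  The second
    element is 1 when the group selector matches the group exactly rather
    than by class compatibility; it ranks e.g. a P-peptide-selective link
    above a generic peptide one at equal integer specificity."""
    if side.comp_id is not None:
        return (2, 1) if side.comp_id == comp_id else None
    if side.group is not None:
        for g in (group, alias_group):
            if g is None:
                continue
            if side.group == g:
                return (1, 1)
        for g in (group, alias_group):
            if g is not None and groups_compatible(side.group, g):
                return (1, 0)
        return None
    return (1, 0)  # wildcard side (gap)


def score_specificity(link: LinkDefinition, comp1: str, group1: ChemGroup,
                      comp2: str, group2: ChemGroup,
                      alias_group1: ChemGroup | None = None,
                      alias_group2: ChemGroup | None = None,
                      ) -> tuple[int, int, bool] | None:
    """Best specificity over both orientations, or None if the link does
    not apply.  Returns (score, exact_group_count, ctx1_is_side1)."""
    best = None
    for orientation in (True, False):
        if orientation:
            s1 = _side_score(link.side1, comp1, group1, alias_group1)
            s2 = _side_score(link.side2, comp2, group2, alias_group2)
        else:
            s1 = _side_score(link.side1, comp2, group2, alias_group2)
            s2 = _side_score(link.side2, comp1, group1, alias_group1)
        if s1 is None or s2 is None:
            continue
        key = (s1[0] + s2[0], s1[1] + s2[1])
        if best is None or key > best[:2]:
            best = (key[0], key[1], orientation)
    return best


def _link_atoms_match(link: LinkDefinition, m: LinkMatch) -> bool:
    """The cross-link bond template must name this candidate's atom pair."""
    for t in link.cross_bonds():
        by_side = {1: [], 2: []}
        for name, side in zip(t.atom_names, t.atom_sides):
            by_side[side].append(name)
        want1, want2 = by_side[1][0], by_side[2][0]
        if (want1 == (m.candidate.std_name1 if m.orientation else m.candidate.std_name2)
                and want2 == (m.candidate.std_name2 if m.orientation
                              else m.candidate.std_name1)):
            return True
    return False


def _resolve_link_atom(m: LinkMatch, side: int, std_name: str) -> AtomSite | None:
    ctx = m.side1_ctx if side == 1 else m.side2_ctx
    alt = m.side1_altloc if side == 1 else m.side2_altloc
    hits = ctx.find_atoms(std_name, alt or None)
    return hits[0] if hits else None


def disambiguate_by_geometry(tied: list[LinkMatch], model: StructureModel,
                             options: Options | None = None) -> LinkMatch:
    """Break a specificity tie by comparing the links' torsion ideals and
    chirality signs with the model geometry; deterministic lexicographic
    tie-break on the link id."""
    options = options or Options()
    tied = sorted(tied, key=lambda m: m.link.link_id)
    scored = []
    for m in tied:
        dev = 0.0
        usable = False
        for t in m.link.templates:
            if t.kind == "torsion":
                atoms = [_resolve_link_atom(m, s, n)
                         for n, s in zip(t.atom_names, t.atom_sides)]
                if any(a is None for a in atoms):
                    dev = float("inf")
                    break
                val = torsion_deg(*[a.position for a in atoms])
                dev += (periodic_delta(val, t.ideal, t.period) / t.sigma) ** 2
                usable = True
            elif t.kind == "chirality":
                atoms = [_resolve_link_atom(m, s, n)
                         for n, s in zip(t.atom_names, t.atom_sides)]
                if any(a is None for a in atoms):
                    dev = float("inf")
                    break
                vol = chiral_volume(*[a.position for a in atoms])
                viol = ((t.sign == "positive" and vol < 0)
                        or (t.sign == "negative" and vol > 0))
                if viol:
                    dev += options.chirality_penalty ** 2
                usable = True
        if not usable and dev == 0.0:
            dev = float("inf")
        scored.append((dev, m))
    finite = [s for s in scored if np.isfinite(s[0])]
    if not finite:
        logger.warning(
            "no geometry available to disambiguate %s; keeping %s",
            [m.link.link_id for _, m in scored], scored[0][1].link.link_id,
        )
        return scored[0][1]
    best_dev = min(d for d, _ in finite)
    # deviations equal to numerical precision count as a tie
    tol = best_dev * 1e-9 + 1e-12
    winners = [m for d, m in finite if d <= best_dev + tol]
    if len(winners) > 1:
        logger.warning(
            "geometry tie between %s; keeping %s (lexicographic)",
            [m.link.link_id for m in winners], winners[0].link.link_id,
        )
    return winners[0]


def match_links(candidates: list[BondCandidate], lib: MonomerLibrary,
                model: StructureModel,
                options: Options | None = None) -> list[LinkMatch]:
    """Assign a link description (or a bond-only fallback) to every
    candidate bond, one match per conformer pairing."""
    options = options or Options()
    matches: list[LinkMatch] = []
    # internal sort by link_id makes the result independent of file order
    all_links = [lib.links[k] for k in sorted(lib.links)]
    for cand in candidates:
        d1, d2 = cand.ctx1.definition, cand.ctx2.definition
        ag1 = d1.alias.group_context if d1.alias else None
        ag2 = d2.alias.group_context if d2.alias else None
        if cand.named_link_id:
            link = lib.link(cand.named_link_id)
            sc = score_specificity(link, d1.comp_id, d1.group, d2.comp_id,
                                   d2.group, ag1, ag2)
            orientation = sc[2] if sc else True
            for pair in cand.altloc_pairing:
                matches.append(LinkMatch(cand, link, orientation,
                                         specificity=sc[0] if sc else 0,
                                         exactness=sc[1] if sc else 0,
                                         altlocs=pair))
            continue
        scores = []
        for link in all_links:
            if link.link_id == GAP_LINK_ID:
                continue
            sc = score_specificity(link, d1.comp_id, d1.group, d2.comp_id,
                                   d2.group, ag1, ag2)
            if sc is not None:
                scores.append((sc[0], sc[1], link, sc[2]))
        for pair in cand.altloc_pairing:
            pair_matches = [
                LinkMatch(cand, link, orientation, specificity=s, exactness=e,
                          altlocs=pair)
                for s, e, link, orientation in scores
            ]
            pair_matches = [m for m in pair_matches if _link_atoms_match(m.link, m)]
            if not pair_matches:
                matches.append(LinkMatch(cand, None, True, altlocs=pair,
                                         fallback=True))
                logger.info(
                    "no link description for %s(%s)-%s(%s); bond-length "
                    "fallback", d1.comp_id, cand.std_name1, d2.comp_id,
                    cand.std_name2,
                )
                continue
            top = max((m.specificity, m.exactness) for m in pair_matches)
            tied = [m for m in pair_matches
                    if (m.specificity, m.exactness) == top]
            if len(tied) == 1:
                matches.append(tied[0])
            else:
                matches.append(disambiguate_by_geometry(tied, model, options))
    return matches
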
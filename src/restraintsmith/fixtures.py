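"""Self-contained mini monomer library and toy models.

Everything other modules need for testing and demonstration is generated
here: a small dictionary (alanine, glycine, cysteine, a citrulline-like
peptide monomer carrying an alias table, two deoxynucleotides, an
ORP-like nucleotide with nonstandard names, the peptide/phosphodiester/
disulfide links and their modifications) plus toy coordinate models built
from ideal internal coordinates.

The handful of ideal values that are published for these components (the
free-acid C—O distance, the DEL-OXT modified C—O distance, the peptide-link
CA—C—N / C—N—CA angles, the phosphodiester O3'—P—OP2 / O3'—P—O5' angles)
are kept in :data:`TRANSCRIPTION_TABLE` as the single source of truth and
asserted against the generated dictionary by the test-suite.  All other
numbers are ordinary stereochemistry taken from standard tabulations.

The CIR and ORX monomers are synthetic stand-ins: CIR's side chain is
truncated to a methyl and ORX is a generic deoxynucleotide with renamed
atoms; they reproduce the *naming* situation of the real components, not
their full chemistry.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ._geom import chiral_volume, place_atom, torsion_deg
from .errors import ModelError
from .monomer_library import (
    AliasTable,
    AtomSpec,
    ChemGroup,
    ChemMod,
    ChemModAction,
    LinkDefinition,
    LinkSide,
    MonomerDefinition,
    RestraintTemplate,
    links_to_cif,
    mods_to_cif,
    monomer_to_cif,
)
from .model_io import AtomAddress, AtomSite, Chain, ConnRecord, Residue, StructureModel

# Values printed in the published description of this library mechanism;
# everything the acceptance checks compare against lives here.
TRANSCRIPTION_TABLE: dict[str, float] = {
    "ALA C-O bond ideal (A)": 1.25,
    "DEL-OXT modified C-O ideal (A)": 1.23,
    "peptide link CA-C-N ideal (deg)": 115.9,
    "peptide link C-N-CA ideal (deg)": 122.1,
    "phosphodiester link O3'-P-OP2 ideal (deg)": 108.5,
    "phosphodiester link O3'-P-O5' ideal (deg)": 101.1,
}

# Ordinary stereochemistry (standard tabulations, NOT published alongside the
# library mechanism): hydrogen electron-cloud/nucleus distances, backbone
# bonds and angles, torsion defaults used by the model builders.
H_BONDS = {  # parent type -> (cloud, sigma, nucleus)
    "N": (0.86, 0.02, 1.02),
    "C_SP3": (0.97, 0.02, 1.09),
    "O": (0.82, 0.02, 0.97),
    "S": (1.20, 0.02, 1.34),
}
PEPTIDE_CN = 1.329
PHOSPHODIESTER_O3P = 1.607


def _t(kind, names, ideal=None, sigma=0.02, **kw) -> RestraintTemplate:
    return RestraintTemplate(kind=kind, atom_names=tuple(names), ideal=ideal,
                             sigma=sigma, **kw)


def _bond(a, b, ideal, sigma=0.02, nucleus=None):
    return _t("bond", (a, b), ideal, sigma, ideal_nucleus=nucleus)


def _angle(a, b, c, ideal, sigma=2.0):
    return _t("angle", (a, b, c), ideal, sigma)


# --- amino-acid monomers -----------------------------------------------------


def _amino_acid(comp_id: str, kind: str) -> MonomerDefinition:
    """Standard-named amino-acid definition; kind in {ala, gly, cys}."""
    hn = H_BONDS["N"]
    hc = H_BONDS["C_SP3"]
    atoms = [
        AtomSpec("N", "N", "NT3", 1.0),
        AtomSpec("H", "H", "H"),
        AtomSpec("H2", "H", "H", is_leaving=True),
        AtomSpec("H3", "H", "H", is_leaving=True),
        AtomSpec("CA", "C", "CH1"),
        AtomSpec("C", "C", "C"),
        AtomSpec("O", "O", "O"),
        AtomSpec("OXT", "O", "OC", -1.0, is_leaving=True),
    ]
    tpl = [
        _bond("N", "CA", 1.466, 0.015),
        _bond("CA", "C", 1.525, 0.013),
        _bond("C", "O", 1.25, 0.019),
        _bond("C", "OXT", 1.25, 0.019),
        _bond("N", "H", hn[0], hn[1], hn[2]),
        _bond("N", "H2", hn[0], hn[1], hn[2]),
        _bond("N", "H3", hn[0], hn[1], hn[2]),
        _angle("N", "CA", "C", 111.0, 2.8),
        _angle("CA", "C", "O", 120.8, 1.7),
        _angle("CA", "C", "OXT", 116.2, 1.8),
        _angle("O", "C", "OXT", 123.0, 1.6),
        _angle("H", "N", "CA", 109.9, 2.0),
        _angle("H2", "N", "CA", 109.9, 2.0),
        _angle("H3", "N", "CA", 109.9, 2.0),
        _angle("H", "N", "H2", 107.9, 2.2),
        _angle("H", "N", "H3", 107.9, 2.2),
        _angle("H2", "N", "H3", 107.9, 2.2),
        _t("torsion", ("H", "N", "CA", "C"), 180.0, 10.0, period=3,
           label="chi_N"),
        _t("plane", ("CA", "C", "O", "OXT"), sigma=0.02, label="plan-1"),
    ]
    if kind == "gly":
        atoms += [AtomSpec("HA2", "H", "H"), AtomSpec("HA3", "H", "H")]
        tpl += [
            _bond("CA", "HA2", hc[0], hc[1], hc[2]),
            _bond("CA", "HA3", hc[0], hc[1], hc[2]),
            _angle("N", "CA", "HA2", 109.3, 1.5),
            _angle("N", "CA", "HA3", 109.3, 1.5),
            _angle("C", "CA", "HA2", 109.3, 1.5),
            _angle("C", "CA", "HA3", 109.3, 1.5),
            _angle("HA2", "CA", "HA3", 107.9, 1.8),
        ]
    else:
        atoms += [AtomSpec("HA", "H", "H"), AtomSpec("CB", "C", "CH3")]
        tpl += [
            _bond("CA", "HA", hc[0], hc[1], hc[2]),
            _bond("CA", "CB", 1.521, 0.015),
            _angle("N", "CA", "CB", 110.4, 2.0),
            _angle("CB", "CA", "C", 110.5, 2.0),
            _angle("N", "CA", "HA", 108.6, 1.5),
            _angle("C", "CA", "HA", 108.8, 1.5),
            _angle("CB", "CA", "HA", 109.3, 1.5),
            _t("chirality", ("CA", "N", "C", "CB"), sign="negative",
               sigma=0.2, label="chir_01"),
        ]
    if kind == "ala":
        atoms += [AtomSpec("HB1", "H", "H"), AtomSpec("HB2", "H", "H"),
                  AtomSpec("HB3", "H", "H")]
        for h in ("HB1", "HB2", "HB3"):
            tpl += [
                _bond("CB", h, 0.96, 0.02, 1.09),
                _angle("CA", "CB", h, 109.5, 1.5),
            ]
        tpl += [
            _angle("HB1", "CB", "HB2", 109.4, 1.8),
            _angle("HB1", "CB", "HB3", 109.4, 1.8),
            _angle("HB2", "CB", "HB3", 109.4, 1.8),
            _t("torsion", ("HB1", "CB", "CA", "N"), 180.0, 10.0, period=3,
               label="chi_CB"),
        ]
    elif kind == "cys":
        hs = H_BONDS["S"]
        atoms += [AtomSpec("HB2", "H", "H"), AtomSpec("HB3", "H", "H"),
                  AtomSpec("SG", "S", "SH1"), AtomSpec("HG", "H", "H")]
        tpl += [
            _bond("CB", "HB2", 0.97, 0.02, 1.09),
            _bond("CB", "HB3", 0.97, 0.02, 1.09),
            _bond("CB", "SG", 1.808, 0.02),
            _bond("SG", "HG", hs[0], hs[1], hs[2]),
            _angle("CA", "CB", "SG", 114.4, 2.3),
            _angle("CA", "CB", "HB2", 109.0, 1.5),
            _angle("CA", "CB", "HB3", 109.0, 1.5),
            _angle("HB2", "CB", "HB3", 109.0, 1.8),
            _angle("HB2", "CB", "SG", 108.0, 1.5),
            _angle("HB3", "CB", "SG", 108.0, 1.5),
            _angle("CB", "SG", "HG", 98.0, 2.0),
        ]
    d = MonomerDefinition(comp_id=comp_id, group=ChemGroup.PEPTIDE,
                          atoms=atoms, templates=tpl)
    d.validate()
    return d


# CIR: a peptide monomer whose main-chain atoms carry nonstandard names.
# Mapping from nonstandard names to the standard peptide names.
CIR_ALIAS: dict[str, str] = {
    "N1": "N", "HN1": "H", "HN2": "H2", "HN3": "H3",
    "C2": "CA", "HC2": "HA", "C3": "CB",
    "H31": "HB1", "H32": "HB2", "H33": "HB3",
    "C1": "C", "O1": "O", "O2": "OXT",
}


def _rename_def(d: MonomerDefinition, std_to_local: dict[str, str]) -> None:
    for a in d.atoms:
        a.name = std_to_local.get(a.name, a.name)
    d.templates = [t.rename(std_to_local) for t in d.templates]


def make_cir(variant: str = "alias") -> MonomerDefinition:
    """Synthetic citrulline-like monomer (side chain truncated to a methyl).

    variant: 'alias' (nonstandard names + alias table), 'renamed' (standard
    names, no alias), 'noalias' (nonstandard names, no alias).
    """
    d = _amino_acid("CIR", "ala")
    if variant == "renamed":
        return d
    std_to_local = {v: k for k, v in CIR_ALIAS.items()}
    _rename_def(d, std_to_local)
    if variant == "alias":
        d.alias = AliasTable(group_context=ChemGroup.PEPTIDE, pairs=dict(CIR_ALIAS))
    elif variant != "noalias":
        raise ValueError(f"unknown CIR variant {variant!r}")
    d.validate()
    return d


# --- nucleotide monomers -----------------------------------------------------

_NUC_BACKBONE = [
    # bonds (a, b, ideal, sigma)
    ("P", "OP1", 1.485, 0.017), ("P", "OP2", 1.485, 0.017),
    ("P", "OP3", 1.610, 0.020), ("P", "O5'", 1.593, 0.015),
    ("O5'", "C5'", 1.440, 0.016), ("C5'", "C4'", 1.511, 0.015),
    ("C4'", "O4'", 1.446, 0.014), ("C4'", "C3'", 1.524, 0.015),
    ("C3'", "O3'", 1.422, 0.015), ("C3'", "C2'", 1.525, 0.015),
    ("C2'", "C1'", 1.520, 0.015), ("C1'", "O4'", 1.415, 0.014),
    ("C1'", "N1", 1.470, 0.015),
]
_NUC_ANGLES = [
    ("OP1", "P", "OP2", 119.6, 1.5), ("OP1", "P", "O5'", 108.1, 3.0),
    ("OP2", "P", "O5'", 108.3, 3.0), ("OP3", "P", "O5'", 105.2, 3.0),
    ("OP1", "P", "OP3", 112.0, 3.0), ("OP2", "P", "OP3", 112.0, 3.0),
    ("P", "O5'", "C5'", 120.9, 1.6), ("O5'", "C5'", "C4'", 111.0, 2.0),
    ("C5'", "C4'", "C3'", 115.2, 1.6), ("C5'", "C4'", "O4'", 109.2, 1.5),
    ("O4'", "C4'", "C3'", 105.6, 1.0), ("C4'", "C3'", "O3'", 110.3, 2.2),
    ("C4'", "C3'", "C2'", 103.1, 0.9), ("O3'", "C3'", "C2'", 110.5, 2.5),
    ("C3'", "C2'", "C1'", 102.7, 1.0), ("C2'", "C1'", "O4'", 106.1, 1.0),
    ("C2'", "C1'", "N1", 113.4, 1.5), ("O4'", "C1'", "N1", 108.0, 1.0),
    ("C1'", "O4'", "C4'", 109.9, 1.0), ("C3'", "O3'", "HO3'", 109.0, 3.0),
]


def _nucleotide(comp_id: str) -> MonomerDefinition:
    ho = H_BONDS["O"]
    atoms = [
        AtomSpec("P", "P", "P"),
        AtomSpec("OP1", "O", "OP", -0.5), AtomSpec("OP2", "O", "OP", -0.5),
        AtomSpec("OP3", "O", "OP", -0.5, is_leaving=True),
        AtomSpec("O5'", "O", "O2"), AtomSpec("C5'", "C", "CH2"),
        AtomSpec("C4'", "C", "CH1"), AtomSpec("O4'", "O", "O2"),
        AtomSpec("C3'", "C", "CH1"), AtomSpec("O3'", "O", "OH1"),
        AtomSpec("HO3'", "H", "H", is_leaving=True),
        AtomSpec("C2'", "C", "CH2"), AtomSpec("C1'", "C", "CH1"),
        AtomSpec("N1", "N", "NR"),
    ]
    tpl = [_bond(a, b, v, s) for a, b, v, s in _NUC_BACKBONE]
    tpl.append(_bond("O3'", "HO3'", ho[0], ho[1], ho[2]))
    tpl += [_angle(a, b, c, v, s) for a, b, c, v, s in _NUC_ANGLES]
    d = MonomerDefinition(comp_id=comp_id, group=ChemGroup.DNA,
                          atoms=atoms, templates=tpl)
    d.validate()
    return d


# ORX: ORP-like deoxynucleotide with nonstandard names; the alias table is
# deliberately partial (the base stub N1 is not mapped).
ORX_ALIAS: dict[str, str] = {
    "P1": "P", "O1P": "OP1", "O2P": "OP2", "O3P": "OP3",
    "O51": "O5'", "C51": "C5'", "C41": "C4'", "O41": "O4'",
    "C31": "C3'", "O31": "O3'", "HO31": "HO3'", "C21": "C2'", "C11": "C1'",
}


def make_orx(variant: str = "alias") -> MonomerDefinition:
    """Synthetic ORP-like nucleotide with nonstandard atom names."""
    d = _nucleotide("ORX")
    if variant == "renamed":
        return d
    std_to_local = {v: k for k, v in ORX_ALIAS.items()}
    _rename_def(d, std_to_local)
    if variant == "alias":
        d.alias = AliasTable(group_context=ChemGroup.DNA, pairs=dict(ORX_ALIAS))
    elif variant != "noalias":
        raise ValueError(f"unknown ORX variant {variant!r}")
    d.validate()
    return d


# --- links and modifications -------------------------------------------------


def _side(group=None, comp=None, mod=None) -> LinkSide:
    return LinkSide(comp_id=comp, group=group, mod_id=mod)


def _lt(kind, pairs, ideal=None, sigma=0.02, **kw) -> RestraintTemplate:
    names = tuple(n for _, n in pairs)
    sides = tuple(s for s, _ in pairs)
    return RestraintTemplate(kind=kind, atom_names=names, atom_sides=sides,
                             ideal=ideal, sigma=sigma, **kw)


def make_links() -> list[LinkDefinition]:
    peptide_templates = [
        _lt("bond", [(1, "C"), (2, "N")], PEPTIDE_CN, 0.014),
        _lt("angle", [(1, "CA"), (1, "C"), (2, "N")],
            TRANSCRIPTION_TABLE["peptide link CA-C-N ideal (deg)"], 1.6),
        _lt("angle", [(1, "O"), (1, "C"), (2, "N")], 123.0, 1.6),
        _lt("angle", [(1, "C"), (2, "N"), (2, "CA")],
            TRANSCRIPTION_TABLE["peptide link C-N-CA ideal (deg)"], 1.7),
        _lt("angle", [(1, "C"), (2, "N"), (2, "H")], 119.2, 2.0),
        _lt("plane", [(1, "CA"), (1, "C"), (1, "O"), (2, "N"), (2, "H"),
                      (2, "CA")], sigma=0.02, label="plan-1"),
    ]
    trans = LinkDefinition(
        "TRANS",
        _side(group=ChemGroup.PEPTIDE, mod="DEL-OXT"),
        _side(group=ChemGroup.PEPTIDE, mod="DEL-NH3"),
        peptide_templates
        + [_lt("torsion", [(1, "CA"), (1, "C"), (2, "N"), (2, "CA")],
               180.0, 5.0, label="omega")],
    )
    cis = LinkDefinition(
        "CIS",
        _side(group=ChemGroup.PEPTIDE, mod="DEL-OXT"),
        _side(group=ChemGroup.PEPTIDE, mod="DEL-NH3"),
        [RestraintTemplate(**{**t.__dict__}) for t in peptide_templates]
        + [_lt("torsion", [(1, "CA"), (1, "C"), (2, "N"), (2, "CA")],
               0.0, 5.0, label="omega")],
    )
    ptrans = LinkDefinition(
        "PTRANS",
        _side(group=ChemGroup.PEPTIDE, mod="DEL-OXT"),
        _side(group=ChemGroup.P_PEPTIDE),
        [
            _lt("bond", [(1, "C"), (2, "N")], 1.341, 0.016),
            _lt("angle", [(1, "CA"), (1, "C"), (2, "N")], 117.0, 1.6),
            _lt("angle", [(1, "C"), (2, "N"), (2, "CA")], 122.6, 2.0),
            _lt("torsion", [(1, "CA"), (1, "C"), (2, "N"), (2, "CA")],
                180.0, 5.0, label="omega"),
        ],
    )
    pept_pro = LinkDefinition(
        "PEPT-PRO",
        _side(group=ChemGroup.PEPTIDE, mod="DEL-OXT"),
        _side(comp="PRO"),
        [_lt("bond", [(1, "C"), (2, "N")], 1.341, 0.016)],
    )
    lys_pro = LinkDefinition(
        "LYS-PRO",
        _side(comp="LYS", mod="DEL-OXT"),
        _side(comp="PRO"),
        [_lt("bond", [(1, "C"), (2, "N")], 1.341, 0.016)],
    )
    ss = LinkDefinition(
        "SS",
        _side(comp="CYS", mod="DEL-HG"),
        _side(comp="CYS", mod="DEL-HG"),
        [
            _lt("bond", [(1, "SG"), (2, "SG")], 2.033, 0.02),
            _lt("angle", [(1, "CB"), (1, "SG"), (2, "SG")], 103.8, 1.8),
            _lt("angle", [(1, "SG"), (2, "SG"), (2, "CB")], 103.8, 1.8),
            _lt("torsion", [(1, "CB"), (1, "SG"), (2, "SG"), (2, "CB")],
                90.0, 10.0, period=2, label="ss"),
        ],
    )
    nuc = LinkDefinition(
        "NUC",
        _side(group=ChemGroup.DNA, mod="DEL-HO3"),
        _side(group=ChemGroup.DNA, mod="DEL-OP3"),
        [
            _lt("bond", [(1, "O3'"), (2, "P")], PHOSPHODIESTER_O3P, 0.015),
            _lt("angle", [(1, "C3'"), (1, "O3'"), (2, "P")], 119.7, 1.5),
            _lt("angle", [(1, "O3'"), (2, "P"), (2, "OP1")], 108.1, 3.0),
            _lt("angle", [(1, "O3'"), (2, "P"), (2, "OP2")],
                TRANSCRIPTION_TABLE["phosphodiester link O3'-P-OP2 ideal (deg)"],
                3.0),
            _lt("angle", [(1, "O3'"), (2, "P"), (2, "O5'")],
                TRANSCRIPTION_TABLE["phosphodiester link O3'-P-O5' ideal (deg)"],
                3.0),
        ],
    )
    gap = LinkDefinition("gap", _side(), _side(), [])
    links = [trans, cis, ptrans, pept_pro, lys_pro, ss, nuc, gap]
    for l in links:
        l.validate()
    return links


def make_mods() -> list[ChemMod]:
    return [
        ChemMod("DEL-OXT", [
            ChemModAction(verb="delete_atom", name="OXT"),
            ChemModAction(
                verb="change_restraint", kind="bond", atom_names=("C", "O"),
                changes={"ideal":
                         TRANSCRIPTION_TABLE["DEL-OXT modified C-O ideal (A)"]},
            ),
        ]),
        ChemMod("DEL-NH3", [
            ChemModAction(verb="delete_atom", name="H2"),
            ChemModAction(verb="delete_atom", name="H3"),
            ChemModAction(verb="change_atom", name="N",
                          changes={"charge": 0.0, "chemical_type": "NH1"}),
            # the remaining H becomes a planar amide proton
            ChemModAction(verb="delete_restraint", kind="torsion",
                          atom_names=("H", "N", "CA", "C")),
            ChemModAction(verb="change_restraint", kind="angle",
                          atom_names=("H", "N", "CA"),
                          changes={"ideal": 118.2}),
        ]),
        ChemMod("DEL-HG", [ChemModAction(verb="delete_atom", name="HG")]),
        ChemMod("DEL-HO3", [ChemModAction(verb="delete_atom", name="HO3'")]),
        ChemMod("DEL-OP3", [ChemModAction(verb="delete_atom", name="OP3")]),
    ]


def make_mini_library(out_dir: str | Path, cir_variant: str = "alias",
                      orx_variant: str = "alias") -> Path:
    """Write the mini library under ``out_dir`` in the documented layout:
    ``<root>/<first-letter-lowercased>/<COMP_ID>.cif`` plus
    ``<root>/list/links.cif`` and ``<root>/list/mods.cif``."""
    root = Path(out_dir)
    monomers = [
        _amino_acid("ALA", "ala"),
        _amino_acid("GLY", "gly"),
        _amino_acid("CYS", "cys"),
        make_cir(cir_variant),
        _nucleotide("DA"),
        _nucleotide("DC"),
        make_orx(orx_variant),
    ]
    for d in monomers:
        sub = root / d.comp_id[0].lower()
        sub.mkdir(parents=True, exist_ok=True)
        (sub / f"{d.comp_id}.cif").write_text(monomer_to_cif(d))
    (root / "list").mkdir(parents=True, exist_ok=True)
    (root / "list" / "links.cif").write_text(links_to_cif(make_links()))
    (root / "list" / "mods.cif").write_text(mods_to_cif(make_mods()))
    return root


# --- toy models --------------------------------------------------------------

_KNOWN_PEPTIDES = {"ALA", "GLY", "CYS", "CIR"}
_KNOWN_NUCLEOTIDES = {"DA", "DC", "ORX"}


def _build_peptide_positions(sequence: list[str], omegas: list[float],
                             phi: float = -139.0, psi: float = 135.0):
    """Heavy-atom positions per residue from ideal internal coordinates."""
    res_pos: list[dict[str, np.ndarray]] = []
    n = len(sequence)
    for i, comp in enumerate(sequence):
        pos: dict[str, np.ndarray] = {}
        if i == 0:
            pos["N"] = np.zeros(3)
            pos["CA"] = np.array([1.466, 0.0, 0.0])
            pos["C"] = place_atom(np.array([0.0, 1.0, 0.0]), pos["N"],
                                  pos["CA"], 1.525, 111.0, 0.0)
        else:
            prev = res_pos[i - 1]
            omega = omegas[i - 1]
            pos["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                  PEPTIDE_CN, 115.9, psi)
            pos["CA"] = place_atom(prev["CA"], prev["C"], pos["N"],
                                   1.466, 122.1, omega)
            pos["C"] = place_atom(prev["C"], pos["N"], pos["CA"],
                                  1.525, 111.0, phi)
        linked_forward = i < n - 1
        pos["O"] = place_atom(pos["N"], pos["CA"], pos["C"],
                              1.23 if linked_forward else 1.25, 120.8,
                              psi + 180.0)
        if not linked_forward:
            pos["OXT"] = place_atom(pos["N"], pos["CA"], pos["C"],
                                    1.25, 116.2, psi)
        if comp in ("ALA", "CYS", "CIR"):
            # choose the CB branch that satisfies the L-configuration
            # (negative chiral volume for the N, C, CB neighbor order)
            for t in (122.0, -122.0):
                cb = place_atom(pos["C"], pos["N"], pos["CA"], 1.521, 110.4, t)
                if chiral_volume(pos["CA"], pos["N"], pos["C"], cb) < 0:
                    pos["CB"] = cb
                    break
            else:  # pragma: no cover - construction guarantees a branch
                raise ModelError("could not satisfy CB chirality")
        if comp == "CYS":
            pos["SG"] = place_atom(pos["N"], pos["CA"], pos["CB"],
                                   1.808, 114.4, -65.0)
        res_pos.append(pos)
    return res_pos


def _build_nucleic_positions(sequence: list[str]):
    res_pos: list[dict[str, np.ndarray]] = []
    # B-DNA-like backbone torsions
    eps, zeta, alpha, beta, gamma, delta = -133.0, -157.0, -63.0, 171.0, 54.0, 123.0
    for i, _comp in enumerate(sequence):
        pos: dict[str, np.ndarray] = {}
        if i == 0:
            pos["P"] = np.zeros(3)
            pos["O5'"] = np.array([1.593, 0.0, 0.0])
            pos["C5'"] = place_atom(np.array([0.0, 1.0, 0.0]), pos["P"],
                                    pos["O5'"], 1.44, 120.9, 60.0)
        else:
            prev = res_pos[i - 1]
            pos["P"] = place_atom(prev["C4'"], prev["C3'"], prev["O3'"],
                                  PHOSPHODIESTER_O3P, 119.7, eps)
            pos["O5'"] = place_atom(prev["C3'"], prev["O3'"], pos["P"],
                                    1.593, 101.1, zeta)
            pos["C5'"] = place_atom(prev["O3'"], pos["P"], pos["O5'"],
                                    1.44, 120.9, alpha)
        pos["C4'"] = place_atom(pos["P"], pos["O5'"], pos["C5'"],
                                1.511, 111.0, beta)
        pos["C3'"] = place_atom(pos["O5'"], pos["C5'"], pos["C4'"],
                                1.524, 115.2, gamma)
        pos["O3'"] = place_atom(pos["C5'"], pos["C4'"], pos["C3'"],
                                1.422, 110.3, delta)
        # phosphate oxygens occupy the tetrahedral slots left free around P
        if i == 0:
            slots = [(-60.0, "OP1"), (60.0, "OP2"), (180.0, "OP3")]
        else:
            t0 = torsion_deg(res_pos[i - 1]["O3'"], pos["P"], pos["O5'"],
                             pos["C5'"])
            slots = [(t0 + 120.0, "OP1"), (t0 - 120.0, "OP2")]
        for tor, name in slots:
            pos[name] = place_atom(pos["C5'"], pos["O5'"], pos["P"],
                                   1.485 if name != "OP3" else 1.61,
                                   108.2 if name != "OP3" else 105.2, tor)
        # furanose ring walked C3'->C2'->C1'->O4'; the three torsions were
        # solved once so that the O4'-C4' closure bond and its angles come
        # out at their ideals
        pos["C2'"] = place_atom(pos["C5'"], pos["C4'"], pos["C3'"],
                                1.525, 103.1, -141.06)
        pos["C1'"] = place_atom(pos["C4'"], pos["C3'"], pos["C2'"],
                                1.52, 102.7, 30.93)
        pos["O4'"] = place_atom(pos["C3'"], pos["C2'"], pos["C1'"],
                                1.415, 106.1, -32.61)
        pos["N1"] = place_atom(pos["C3'"], pos["C2'"], pos["C1'"],
                               1.47, 113.4, 115.0)
        res_pos.append(pos)
    return res_pos


_PEPTIDE_ATOM_ORDER = ["N", "CA", "C", "O", "CB", "SG", "OXT"]
_NUC_ATOM_ORDER = ["P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'",
                   "C3'", "O3'", "C2'", "C1'", "N1"]
_ELEMENTS = {"N": "N", "O": "O", "P": "P", "S": "S"}


def _element_of(std_name: str) -> str:
    return _ELEMENTS.get(std_name[0], "C")


def _positions_to_model(sequence, res_positions, chain_id="A",
                        name_maps=None, noise=0.0, seed=0,
                        order=None) -> StructureModel:
    rng = np.random.default_rng(seed)
    chain = Chain(chain_id=chain_id)
    order = order or _PEPTIDE_ATOM_ORDER
    for i, (comp, pos) in enumerate(zip(sequence, res_positions), start=1):
        res = Residue(seq_id=i, comp_id=comp)
        mapping = (name_maps or {}).get(comp, {})
        for std_name in order:
            if std_name not in pos:
                continue
            p = pos[std_name]
            if noise > 0:
                p = p + rng.normal(0.0, noise, 3)
            res.atoms.append(AtomSite(
                name=mapping.get(std_name, std_name),
                element=_element_of(std_name), position=p,
            ))
        chain.residues.append(res)
    model = StructureModel(chains=[chain])
    return model


def build_peptide_model(sequence: list[str], omegas: list[float] | None = None,
                        noise: float = 0.0, seed: int = 0,
                        cir_names: str = "nonstandard",
                        chain_id: str = "A") -> StructureModel:
    for comp in sequence:
        if comp not in _KNOWN_PEPTIDES:
            raise ModelError(f"unknown fixture peptide monomer {comp!r}")
    omegas = omegas if omegas is not None else [180.0] * (len(sequence) - 1)
    res_pos = _build_peptide_positions(sequence, omegas)
    name_maps = {}
    if cir_names == "nonstandard":
        name_maps["CIR"] = {v: k for k, v in CIR_ALIAS.items()}
    return _positions_to_model(sequence, res_pos, chain_id=chain_id,
                               name_maps=name_maps, noise=noise, seed=seed)


def build_nucleic_model(sequence: list[str], noise: float = 0.0, seed: int = 0,
                        orx_names: str = "nonstandard",
                        chain_id: str = "A") -> StructureModel:
    for comp in sequence:
        if comp not in _KNOWN_NUCLEOTIDES:
            raise ModelError(f"unknown fixture nucleotide {comp!r}")
    res_pos = _build_nucleic_positions(sequence)
    # the 5'-terminal OP3 stays; internal phosphates have lost it
    name_maps = {}
    if orx_names == "nonstandard":
        name_maps["ORX"] = {v: k for k, v in ORX_ALIAS.items()}
    return _positions_to_model(sequence, res_pos, chain_id=chain_id,
                               name_maps=name_maps, noise=noise, seed=seed,
                               order=_NUC_ATOM_ORDER)


def _model_name(res: Residue, std: str) -> str:
    """Model atom name for a standard name (nonstandard-named fixtures)."""
    if res.comp_id == "CIR" and res.get_atom(std) is None:
        m = {v: k for k, v in CIR_ALIAS.items()}
        return m.get(std, std)
    if res.comp_id == "ORX" and res.get_atom(std) is None:
        m = {v: k for k, v in ORX_ALIAS.items()}
        return m.get(std, std)
    return std


def _conn_record(model: StructureModel, kind: str, seq1: int, std1: str,
                 seq2: int, std2: str,
                 link_id: str | None = None) -> ConnRecord:
    chain = model.chains[0]
    r1 = next(r for r in chain.residues if r.seq_id == seq1)
    r2 = next(r for r in chain.residues if r.seq_id == seq2)
    return ConnRecord(
        kind=kind,
        atom1=AtomAddress(chain.chain_id, r1.seq_id, r1.icode, r1.comp_id,
                          _model_name(r1, std1)),
        atom2=AtomAddress(chain.chain_id, r2.seq_id, r2.icode, r2.comp_id,
                          _model_name(r2, std2)),
        named_link_id=link_id,
    )


def _gap_record(model: StructureModel, seq1: int, seq2: int) -> ConnRecord:
    return _conn_record(model, "LINKR", seq1, "C", seq2, "N", link_id="gap")


def build_disulfide_model(noise: float = 0.0, seed: int = 0) -> StructureModel:
    """Two free cysteines in chains A and B joined by an SSBOND record."""
    m1 = build_peptide_model(["CYS"], noise=0.0, seed=seed, chain_id="A")
    m2 = build_peptide_model(["CYS"], noise=0.0, seed=seed, chain_id="B")
    sg1 = m1.chains[0].residues[0].get_atom("SG").position
    flip = np.diag([-1.0, 1.0, -1.0])
    sg2_old = m2.chains[0].residues[0].get_atom("SG").position
    target = sg1 + np.array([2.033, 0.0, 0.0])
    for r in m2.chains[0].residues:
        for a in r.atoms:
            a.position = flip @ (a.position - sg2_old) + target
    model = StructureModel(chains=[m1.chains[0], m2.chains[0]])
    if noise > 0:
        rng = np.random.default_rng(seed)
        for _, _, a in model.all_atoms():
            a.position = a.position + rng.normal(0.0, noise, 3)
    model.conn.append(ConnRecord(
        kind="SSBOND",
        atom1=AtomAddress("A", 1, "", "CYS", "SG"),
        atom2=AtomAddress("B", 1, "", "CYS", "SG"),
    ))
    return model


def build_microheterogeneity_model(noise: float = 0.0, seed: int = 0) -> StructureModel:
    """ALA followed by an ALA/GLY microheterogeneous position sharing one N."""
    base = build_peptide_model(["ALA", "ALA"], noise=noise, seed=seed)
    alt = build_peptide_model(["ALA", "GLY"], omegas=[170.0], noise=noise,
                              seed=seed)
    chain = base.chains[0]
    res2a = chain.residues[1]
    for a in res2a.atoms:
        if a.name != "N":
            a.altloc = "A"
            a.occupancy = 0.5
    res2b_src = alt.chains[0].residues[1]
    res2b = Residue(seq_id=2, comp_id="GLY")
    for a in res2b_src.atoms:
        if a.name == "N":
            continue  # the N atom is shared and lives in the ALA conformer
        res2b.atoms.append(AtomSite(name=a.name, element=a.element,
                                    position=a.position, altloc="B",
                                    occupancy=0.5))
    chain.residues.append(res2b)
    return base


def build_cis_trans_altloc_model(noise: float = 0.0, seed: int = 0) -> StructureModel:
    """One shared C atom bonded to two alternative conformations of the next
    residue, one trans (altloc A) and one cis (altloc B)."""
    trans = build_peptide_model(["ALA", "ALA"], omegas=[178.0], noise=noise,
                                seed=seed)
    cis = build_peptide_model(["ALA", "ALA"], omegas=[2.0], noise=noise,
                              seed=seed)
    chain = trans.chains[0]
    res2 = chain.residues[1]
    for a in res2.atoms:
        a.altloc = "A"
        a.occupancy = 0.5
    for a in cis.chains[0].residues[1].atoms:
        res2.atoms.append(AtomSite(name=a.name, element=a.element,
                                   position=a.position, altloc="B",
                                   occupancy=0.5))
    return trans


def build_partial_cleavage_model(noise: float = 0.0, seed: int = 0) -> StructureModel:
    """Residue 2 with conformer A linked to residue 1 and conformer B
    displaced beyond bonding distance (a terminus)."""
    model = build_peptide_model(["ALA", "ALA"], noise=noise, seed=seed)
    res2 = model.chains[0].residues[1]
    shift = np.array([6.0, 0.0, 0.0])
    extra = []
    for a in res2.atoms:
        a.altloc = "A"
        a.occupancy = 0.5
        extra.append(AtomSite(name=a.name, element=a.element,
                              position=a.position + shift, altloc="B",
                              occupancy=0.5))
    res2.atoms.extend(extra)
    return model


def build_odd_link_model(noise: float = 0.0, seed: int = 0) -> StructureModel:
    """An explicit LINK between monomers for which no link description exists
    (peptide CB to nucleotide N1) — exercises the bond-only fallback."""
    pep = build_peptide_model(["ALA"], noise=noise, seed=seed, chain_id="A")
    nuc = build_nucleic_model(["DA"], noise=noise, seed=seed, chain_id="B")
    cb = pep.chains[0].residues[0].get_atom("CB").position
    n1_old = nuc.chains[0].residues[0].get_atom("N1").position
    target = cb + np.array([0.0, 0.0, 1.47])
    for r in nuc.chains[0].residues:
        for a in r.atoms:
            a.position = a.position - n1_old + target
    model = StructureModel(chains=[pep.chains[0], nuc.chains[0]])
    model.conn.append(ConnRecord(
        kind="LINK",
        atom1=AtomAddress("A", 1, "", "ALA", "CB"),
        atom2=AtomAddress("B", 1, "", "DA", "N1"),
    ))
    return model


def make_toy_model(recipe: dict, seed: int = 0) -> StructureModel:
    """Build a toy model from a recipe mapping.

    ``recipe['kind']`` selects the builder: peptide, nucleic, disulfide,
    microheterogeneity, cis_trans_altloc, partial_cleavage, odd_link.
    Coordinates are built from ideal internal coordinates (trans backbone by
    default) and perturbed by Gaussian noise of ``recipe['noise']``
    (default 0.15 Å) under ``seed``.  ``recipe['gap']`` adds a LINKR 'gap'
    record between the two residue numbers given.
    """
    kind = recipe.get("kind", "peptide")
    noise = float(recipe.get("noise", 0.15))
    if kind == "peptide":
        model = build_peptide_model(
            list(recipe["sequence"]), omegas=recipe.get("omegas"),
            noise=noise, seed=seed,
            cir_names=recipe.get("cir_names", "nonstandard"),
        )
    elif kind == "nucleic":
        model = build_nucleic_model(
            list(recipe["sequence"]), noise=noise, seed=seed,
            orx_names=recipe.get("orx_names", "nonstandard"),
        )
    elif kind == "disulfide":
        model = build_disulfide_model(noise=noise, seed=seed)
    elif kind == "microheterogeneity":
        model = build_microheterogeneity_model(noise=noise, seed=seed)
    elif kind == "cis_trans_altloc":
        model = build_cis_trans_altloc_model(noise=noise, seed=seed)
    elif kind == "partial_cleavage":
        model = build_partial_cleavage_model(noise=noise, seed=seed)
    elif kind == "odd_link":
        model = build_odd_link_model(noise=noise, seed=seed)
    else:
        raise ModelError(f"unknown toy-model kind {kind!r}")
    if "gap" in recipe:
        s1, s2 = recipe["gap"]
        model.conn.append(_gap_record(model, s1, s2))
    for spec in recipe.get("conn", []):
        model.conn.append(_conn_record(
            model, spec.get("kind", "LINK"), spec["seq1"], spec["atom1"],
            spec["seq2"], spec["atom2"], link_id=spec.get("link_id"),
        ))
    model.mark_unresolved_conn()
    return model
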
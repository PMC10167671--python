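"""Restraint instantiation, provenance, censuses and the restraint file."""

import numpy as np
import pytest

from restraintsmith import fixtures
from restraintsmith.fixtures import CIR_ALIAS
from restraintsmith.restraints import (
    RestraintSet,
    read_restraint_file,
    restraint_census,
    write_restraint_file,
)


def _bond(rset, seq, names):
    for r in rset.of_kind("bond"):
        if (r.atoms[0].seq_id == seq
                and {a.name for a in r.atoms} == set(names)):
            return r
    return None


def test_isolated_ala_free_acid_ideal(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA"], noise=0.0)
    _, _, _, rset = pipeline(model, lib)
    co = _bond(rset, 1, ("C", "O"))
    assert co.ideal == 1.25
    assert co.provenance == "monomer:ALA"


def test_dipeptide_mod_changes_ideal_and_provenance(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "ALA"], noise=0.0)
    _, _, _, rset = pipeline(model, lib)
    co1 = _bond(rset, 1, ("C", "O"))
    assert co1.ideal == 1.23 and co1.provenance == "mod:DEL-OXT"
    # mod precedence: nothing with the free-acid value survives for residue 1
    assert not any(r.ideal == 1.25 for r in rset.of_kind("bond")
                   if r.atoms[0].seq_id == 1
                   and {a.name for a in r.atoms} == {"C", "O"})
    # the C-terminal residue keeps the free-acid description
    assert _bond(rset, 2, ("C", "O")).ideal == 1.25


def test_peptide_link_angle_ideals(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "ALA"], noise=0.0)
    _, _, _, rset = pipeline(model, lib)
    link_angles = {tuple(a.name for a in r.atoms): r.ideal
                   for r in rset.of_kind("angle")
                   if r.provenance_class() == "link"}
    assert link_angles[("CA", "C", "N")] == 115.9
    assert link_angles[("C", "N", "CA")] == 122.1


def test_phosphodiester_link_angle_ideals(lib, pipeline):
    model = fixtures.build_nucleic_model(["DA", "ORX"], noise=0.0)
    _, _, _, rset = pipeline(model, lib)
    by_names = {tuple(a.name for a in r.atoms): r.ideal
                for r in rset.of_kind("angle")
                if r.provenance_class() == "link"}
    # residue 2 is the nonstandard-named monomer; its atoms appear with
    # their own names after alias resolution
    assert by_names[("O3'", "P1", "O2P")] == 108.5
    assert by_names[("O3'", "P1", "O51")] == 101.1


def test_census_matches_dictionary_row_counts(lib, lib_dir, pipeline):
    """With hydrogens present, every dictionary template of the isolated
    monomer instantiates exactly once."""
    from restraintsmith.monomer_library import parse_monomer_cif
    model = fixtures.build_peptide_model(["ALA"], noise=0.0)
    _, _, _, rset = pipeline(model, lib, hydrogens=True)
    d = parse_monomer_cif((lib_dir / "a" / "ALA.cif").read_text())
    expected = {}
    for t in d.templates:
        expected[t.kind] = expected.get(t.kind, 0) + 1
    census = restraint_census(rset)
    assert census["by_kind"] == dict(sorted(expected.items()))
    assert census["total"] == len(d.templates)


def test_empty_census_is_all_zeros():
    census = restraint_census(RestraintSet())
    assert census == {"total": 0, "by_kind": {}, "by_provenance": {},
                      "by_kind_provenance": {}}


def test_gap_yields_no_link_restraints(lib, pipeline):
    model = fixtures.make_toy_model(
        {"kind": "peptide", "sequence": ["ALA", "ALA"], "noise": 0.0,
         "gap": [1, 2]})
    _, _, _, rset = pipeline(model, lib)
    assert restraint_census(rset)["by_provenance"].get("link", 0) == 0
    assert restraint_census(rset)["by_provenance"].get("mod", 0) == 0


def test_no_dangling_references(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
    _, _, _, rset = pipeline(model, lib, hydrogens=True)
    ids = {id(a) for _, _, a in model.all_atoms()}
    for r in rset:
        for a in r.atoms:
            assert id(a.site) in ids


def test_no_duplicate_restraints(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
    _, _, _, rset = pipeline(model, lib, hydrogens=True)
    keys = [r.dedup_key() for r in rset]
    assert len(keys) == len(set(keys))


def test_alias_transparency_exact(lib, lib_renamed, pipeline):
    """Restraint sets for nonstandard-named + alias vs renamed-standard
    models are identical after applying the name map."""
    aliased = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
    renamed = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0,
                                           cir_names="standard")
    _, _, _, ra = pipeline(aliased, lib, hydrogens=True)
    _, _, _, rr = pipeline(renamed, lib_renamed, hydrogens=True)

    def mapped(sig):
        out = set()
        for kind, atoms, ideal, sigma, period, sign, prov in sig:
            atoms = tuple(
                (c, s, i, comp, CIR_ALIAS.get(n, n) if comp == "CIR" else n, al)
                for c, s, i, comp, n, al in atoms
            )
            out.add((kind, atoms, ideal, sigma, period, sign, prov))
        return out

    assert mapped(ra.comparable()) == mapped(rr.comparable())


def test_monotone_degradation_without_alias(lib, lib_noalias, pipeline):
    """Dropping the alias table can only lose restraints across the
    nonstandard junctions (bond-length fallback), never add any."""
    recipe = {"kind": "peptide", "sequence": ["ALA", "CIR", "ALA"],
              "noise": 0.0,
              "conn": [{"seq1": 1, "atom1": "C", "seq2": 2, "atom2": "N"},
                       {"seq1": 2, "atom1": "C", "seq2": 3, "atom2": "N"}]}
    with_alias = fixtures.make_toy_model(recipe)
    without = fixtures.make_toy_model(recipe)
    _, _, _, ra = pipeline(with_alias, lib)
    _, _, _, rn = pipeline(without, lib_noalias)

    def cross(rset):
        return [r for r in rset if len({a.seq_id for a in r.atoms}) > 1]

    cross_no = cross(rn)
    assert all(r.kind == "bond" and r.provenance == "fallback"
               for r in cross_no)
    assert len(cross_no) <= len(cross(ra))
    ca, cn = restraint_census(ra), restraint_census(rn)
    for kind, n in cn["by_kind"].items():
        assert n <= ca["by_kind"].get(kind, 0) + 2  # fallback bonds only


def test_restraint_file_roundtrip(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
    _, _, _, rset = pipeline(model, lib, hydrogens=True)
    text = write_restraint_file(rset, model)
    back = read_restraint_file(text, model)
    assert back.comparable() == rset.comparable()
    # byte-identical for identical inputs
    assert write_restraint_file(rset, model) == text


def test_restraint_file_contains_one_link_bond_row(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "ALA"], noise=0.0)
    _, _, _, rset = pipeline(model, lib)
    text = write_restraint_file(rset, model)
    link_bond_rows = [ln for ln in text.splitlines()
                      if ln.startswith("A ") and "link:TRANS" in ln
                      and " N " in f" {ln} "]
    link_bonds = [r for r in rset.of_kind("bond")
                  if r.provenance_class() == "link"]
    assert len(link_bonds) == 1


def test_empty_model_gives_header_only_file(lib):
    from restraintsmith.model_io import StructureModel
    model = StructureModel()
    text = write_restraint_file(RestraintSet(), model)
    assert text.startswith("data_restraints")
    assert "loop_" not in text


def test_zero_occupancy_hydrogen_restraints_flagged(lib, pipeline):
    model = fixtures.build_peptide_model(["CYS"], noise=0.0)
    _, _, _, rset = pipeline(model, lib, hydrogens=True)
    hg_bonds = [r for r in rset.of_kind("bond")
                if "HG" in {a.name for a in r.atoms}]
    assert hg_bonds and all(r.zero_occ_h for r in hg_bonds)
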
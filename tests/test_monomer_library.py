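"""Dictionary parsing, modifications and alias tables."""

import pytest

from restraintsmith import fixtures
from restraintsmith.errors import ModApplicationError, SchemaError
from restraintsmith.monomer_library import (
    apply_alias,
    apply_inverse_alias,
    apply_mod,
    monomer_to_cif,
    parse_link_cif,
    parse_monomer_cif,
    parse_monomers,
)


def test_parse_ala_captures_values_and_atoms(lib):
    ala = lib.monomer("ALA")
    assert ala.group.value == "peptide"
    assert ala.bond_between("C", "O").ideal == 1.25
    assert {"N", "CA", "C", "O", "OXT", "CB"} <= ala.atom_names()
    # hydrogen bonds carry both distance flavours
    nh = ala.bond_between("N", "H")
    assert nh.ideal == 0.86 and nh.ideal_nucleus == 1.02


def test_parse_cir_alias_table(lib):
    cir = lib.monomer("CIR")
    assert cir.alias is not None
    assert cir.alias.pairs["C1"] == "C"
    assert cir.alias.group_context.value == "peptide"
    # bijective both ways
    inv = cir.alias.inverse_pairs()
    assert len(inv) == len(cir.alias.pairs)


def test_atoms_only_block_parses_with_empty_templates():
    doc = """
data_comp_list
loop_
_chem_comp.id
_chem_comp.group
XXX non-polymer
data_comp_XXX
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
XXX C1 C
XXX O1 O
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_dist
_chem_comp_bond.value_dist_esd
XXX C1 O1 1.43 0.02
"""
    d = parse_monomer_cif(doc)
    assert d.comp_id == "XXX"
    assert not d.templates_of("angle") and not d.templates_of("torsion")


@pytest.mark.parametrize("mutation, message", [
    ("XXX C1 C", "duplicate atom name"),
    ("XXX ZZ O", "unknown atom"),
])
def test_schema_errors_name_the_offender(mutation, message):
    doc = f"""
data_comp_BAD
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
BAD C1 C
{mutation.replace('XXX', 'BAD') if 'ZZ' not in mutation else 'BAD O1 O'}
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_dist
_chem_comp_bond.value_dist_esd
BAD C1 {'O1' if 'duplicate' in message else 'ZZ'} 1.4 0.02
"""
    with pytest.raises(SchemaError, match=message.split()[0]):
        parse_monomer_cif(doc)


def test_non_bijective_alias_rejected():
    doc = """
data_comp_BAD
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
BAD C1 C
BAD C2 C
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_dist
_chem_comp_bond.value_dist_esd
BAD C1 C2 1.5 0.02
loop_
_chem_comp_alias.comp_id
_chem_comp_alias.group
_chem_comp_alias.atom_id
_chem_comp_alias.atom_id_standard
BAD peptide C1 CA
BAD peptide C2 CA
"""
    with pytest.raises(SchemaError, match="injective"):
        parse_monomer_cif(doc)


def test_parse_trans_link_sides_and_templates(lib):
    trans = lib.links["TRANS"]
    assert trans.side1.group.value == "peptide"
    assert trans.side1.mod_id == "DEL-OXT"
    assert trans.side2.mod_id == "DEL-NH3"
    cross = trans.cross_bonds()
    assert len(cross) == 1
    assert set(zip(cross[0].atom_names, cross[0].atom_sides)) == {("C", 1),
                                                                  ("N", 2)}


def test_gap_link_has_no_templates(lib):
    assert lib.links["gap"].templates == []


def test_empty_link_document_yields_empty_list():
    assert parse_link_cif("data_nothing\n") == []


def test_apply_mod_del_oxt(lib):
    ala = lib.monomer("ALA")
    before_bonds = len(ala.templates_of("bond"))
    touching = sum(1 for t in ala.templates_of("bond")
                   if "OXT" in t.atom_names)
    out = apply_mod(ala, lib.mod("DEL-OXT"))
    assert out.get_atom("OXT") is None
    assert out.bond_between("C", "O").ideal == 1.23
    assert out.bond_between("C", "O").provenance == "mod:DEL-OXT"
    assert len(out.templates_of("bond")) == before_bonds - touching
    # purity: the base definition is untouched and reapplication agrees
    assert ala.get_atom("OXT") is not None
    assert ala.bond_between("C", "O").ideal == 1.25
    again = apply_mod(ala, lib.mod("DEL-OXT"))
    assert [t.atom_names for t in again.templates] == \
        [t.atom_names for t in out.templates]


def test_identity_mod_is_identity(lib):
    from restraintsmith.monomer_library import ChemMod
    ala = lib.monomer("ALA")
    out = apply_mod(ala, ChemMod("NOOP", []))
    assert out.atom_names() == ala.atom_names()
    assert [t.atom_names for t in out.templates] == \
        [t.atom_names for t in ala.templates]


def test_mod_delete_cascades_no_dangling_references(lib):
    out = apply_mod(lib.monomer("ALA"), lib.mod("DEL-OXT"))
    for t in out.templates:
        assert "OXT" not in t.atom_names


def test_unresolvable_mod_action_raises(lib):
    from restraintsmith.monomer_library import ChemMod, ChemModAction
    bad = ChemMod("BAD", [ChemModAction(verb="delete_atom", name="NOPE")])
    with pytest.raises(ModApplicationError, match="NOPE"):
        apply_mod(lib.monomer("ALA"), bad)


def test_alias_roundtrip_is_identity(lib):
    cir = lib.monomer("CIR")
    std = apply_alias(cir)
    assert {"N", "CA", "C", "O"} <= std.atom_names()
    back = apply_inverse_alias(std)
    assert back.atom_names() == cir.atom_names()
    assert sorted(t.atom_names for t in back.templates) == \
        sorted(t.atom_names for t in cir.templates)


def test_apply_alias_without_table_is_identity(lib):
    ala = lib.monomer("ALA")
    assert apply_alias(ala) is ala


@pytest.mark.parametrize("comp", ["ALA", "GLY", "CYS", "CIR", "DA", "ORX"])
def test_serialize_parse_roundtrip(lib, comp):
    d = lib.monomer(comp)
    d2 = parse_monomer_cif(monomer_to_cif(d))
    assert d2.comp_id == d.comp_id and d2.group == d.group
    assert d2.atom_names() == d.atom_names()
    assert sorted((t.kind, t.atom_names) for t in d2.templates) == \
        sorted((t.kind, t.atom_names) for t in d.templates)
    assert (d2.alias.pairs if d2.alias else None) == \
        (d.alias.pairs if d.alias else None)


def test_gemmi_oracle_agrees_on_emitted_dictionary(lib_dir):
    gemmi = pytest.importorskip("gemmi")
    doc = gemmi.cif.read(str(lib_dir / "a" / "ALA.cif"))
    block = doc.find_block("comp_ALA")
    rows = {(r[0], r[1]): float(r[2]) for r in block.find(
        "_chem_comp_bond.", ["atom_id_1", "atom_id_2", "value_dist"])}
    assert rows[("C", "O")] == 1.25
    assert rows[("N", "CA")] == 1.466


def test_later_documents_override_earlier(lib_dir):
    from restraintsmith.monomer_library import MonomerLibrary
    lib = MonomerLibrary.load(lib_dir)
    user = (lib_dir / "a" / "ALA.cif").read_text().replace("1.25", "1.27")
    lib.add_document(user)
    assert lib.monomer("ALA").bond_between("C", "O").ideal == 1.27
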
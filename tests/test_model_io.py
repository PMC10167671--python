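"""PDB/mmCIF round trips and the hybrid-36 encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from restraintsmith import fixtures
from restraintsmith.errors import FormatError
from restraintsmith.model_io import (
    AtomSite,
    Chain,
    Residue,
    StructureModel,
    hy36_decode,
    hy36_encode,
    models_equivalent,
    read_model,
    write_model,
)


@pytest.mark.parametrize("n, width, expected", [
    (1, 5, "    1"),
    (99999, 5, "99999"),
    (100000, 5, "A0000"),
    (9999, 4, "9999"),
    (10000, 4, "A000"),
])
def test_hy36_reference_points(n, width, expected):
    assert hy36_encode(n, width) == expected
    assert hy36_decode(expected, width) == n


def test_hy36_out_of_range():
    with pytest.raises(ValueError):
        hy36_encode(10 ** 6 + 2 * 26 * 36 ** 4, 5)


@settings(derandomize=True, max_examples=200)
@given(st.integers(min_value=0, max_value=10000 + 2 * 26 * 36 ** 3 - 1))
def test_hy36_roundtrip_width4(n):
    assert hy36_decode(hy36_encode(n, 4), 4) == n


@settings(derandomize=True, max_examples=200)
@given(st.integers(min_value=0, max_value=10 ** 5 + 2 * 26 * 36 ** 4 - 1),
       st.integers(min_value=0, max_value=10 ** 5 + 2 * 26 * 36 ** 4 - 1))
def test_hy36_strictly_increasing(a, b):
    """decode(encode) ordering matches integer ordering across both region
    boundaries."""
    if a == b:
        return
    a, b = sorted((a, b))
    assert hy36_decode(hy36_encode(a, 5), 5) < hy36_decode(hy36_encode(b, 5), 5)


def _all_fixture_models():
    yield fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
    yield fixtures.build_nucleic_model(["DA", "ORX"], noise=0.0)
    yield fixtures.make_toy_model({"kind": "disulfide", "noise": 0.0})
    yield fixtures.make_toy_model({"kind": "cis_trans_altloc", "noise": 0.0})
    yield fixtures.make_toy_model(
        {"kind": "peptide", "sequence": ["ALA", "ALA"], "noise": 0.0,
         "gap": [1, 2]})


@pytest.mark.parametrize("fmt", ["pdb", "mmcif"])
def test_read_write_roundtrip_all_fixtures(fmt):
    for model in _all_fixture_models():
        text = write_model(model, fmt)
        back = read_model(text, fmt)
        assert models_equivalent(model, back)


def test_empty_file_gives_empty_model():
    m = read_model("", "pdb")
    assert m.chains == [] and m.conn == []


def test_linkr_gap_record_survives_pdb():
    model = fixtures.make_toy_model(
        {"kind": "peptide", "sequence": ["ALA", "ALA"], "noise": 0.0,
         "gap": [1, 2]})
    text = write_model(model, "pdb")
    assert "LINKR" in text
    back = read_model(text, "pdb")
    assert back.conn[0].kind == "LINKR"
    assert back.conn[0].named_link_id == "gap"


def test_struct_conn_ccp4_link_id_roundtrip():
    model = fixtures.make_toy_model(
        {"kind": "peptide", "sequence": ["ALA", "ALA"], "noise": 0.0,
         "conn": [{"kind": "LINKR", "seq1": 1, "atom1": "C", "seq2": 2,
                   "atom2": "N", "link_id": "TRANS"}]})
    text = write_model(model, "mmcif")
    back = read_model(text, "mmcif")
    assert back.conn[0].named_link_id == "TRANS"


def test_two_letter_chain_ids_roundtrip():
    model = fixtures.build_peptide_model(["ALA"], noise=0.0, chain_id="AB")
    text = write_model(model, "pdb")
    back = read_model(text, "pdb")
    assert back.chains[0].chain_id == "AB"


def test_three_letter_chain_unrepresentable_in_pdb():
    model = fixtures.build_peptide_model(["ALA"], noise=0.0, chain_id="ABC")
    with pytest.raises(FormatError, match="mmCIF"):
        write_model(model, "pdb")
    # mmCIF accepts it
    back = read_model(write_model(model, "mmcif"), "mmcif")
    assert back.chains[0].chain_id == "ABC"


def test_serial_over_decimal_limit_uses_hybrid36():
    model = fixtures.build_peptide_model(["ALA"], noise=0.0)
    model.chains[0].residues[0].atoms[0].serial = 100000
    text = write_model(model, "pdb")
    assert "ATOM  A0000" in text


def test_serials_below_limit_stay_decimal():
    model = fixtures.build_peptide_model(["ALA"], noise=0.0)
    text = write_model(model, "pdb")
    for line in text.splitlines():
        if line.startswith("ATOM"):
            assert line[6:11].strip().isdigit()


def test_gemmi_oracle_reads_our_pdb(tmp_path):
    gemmi = pytest.importorskip("gemmi")
    model = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
    path = tmp_path / "m.pdb"
    path.write_text(write_model(model, "pdb"))
    st_ = gemmi.read_structure(str(path))
    ours = [(r.comp_id, a.name) for _, r, a in model.all_atoms()]
    theirs = [(res.name, atom.name) for ch in st_[0] for res in ch
              for atom in res]
    assert theirs == ours


def test_unresolved_conn_record_is_flagged():
    model = fixtures.make_toy_model(
        {"kind": "peptide", "sequence": ["ALA", "ALA"], "noise": 0.0})
    from restraintsmith.model_io import AtomAddress, ConnRecord
    model.conn.append(ConnRecord(
        kind="LINK",
        atom1=AtomAddress("A", 1, "", "ALA", "ZZ"),
        atom2=AtomAddress("A", 2, "", "ALA", "N"),
    ))
    model.mark_unresolved_conn()
    assert model.conn[0].unresolved
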
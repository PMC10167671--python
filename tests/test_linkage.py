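"""Covalent-link identification: candidates, specificity, disambiguation."""

import numpy as np
import pytest

from restraintsmith import fixtures
from restraintsmith._geom import periodic_delta, torsion_deg
from restraintsmith.config import Options
from restraintsmith.errors import LinkIdentificationError, SchemaError
from restraintsmith.linkage import (
    disambiguate_by_geometry,
    find_bond_candidates,
    match_links,
    resolve_model,
    score_specificity,
)
from restraintsmith.monomer_library import ChemGroup


def test_implicit_peptide_candidates_via_alias(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
    _, cands, matches, _ = pipeline(model, lib)
    assert len(cands) == 2
    assert all(c.origin == "implicit_polymer" for c in cands)
    assert [m.link.link_id for m in matches] == ["TRANS", "TRANS"]


def test_gap_record_removes_exactly_its_candidate(lib, pipeline):
    model = fixtures.make_toy_model(
        {"kind": "peptide", "sequence": ["ALA", "CIR", "ALA"], "noise": 0.0,
         "gap": [1, 2]})
    _, cands, matches, rset = pipeline(model, lib)
    assert len(cands) == 1
    assert cands[0].ctx1.residue.seq_id == 2
    # the gap contributes no restraints of its own
    assert all(m.link.link_id != "gap" for m in matches)


def test_explicit_link_overrides_distance_check(lib, pipeline):
    model = fixtures.make_toy_model(
        {"kind": "peptide", "sequence": ["ALA", "ALA"], "noise": 0.0,
         "conn": [{"kind": "LINK", "seq1": 1, "atom1": "C", "seq2": 2,
                   "atom2": "N"}]})
    # pull residue 2 far beyond the peptide cutoff
    for a in model.chains[0].residues[1].atoms:
        a.position = a.position + np.array([10.0, 0.0, 0.0])
    _, cands, matches, _ = pipeline(model, lib)
    assert len(cands) == 1
    assert matches and matches[0].link.link_id in ("TRANS", "CIS")


def test_far_residues_without_link_record_give_no_candidate(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "ALA"], noise=0.0)
    for a in model.chains[0].residues[1].atoms:
        a.position = a.position + np.array([10.0, 0.0, 0.0])
    _, cands, _, _ = pipeline(model, lib)
    assert cands == []


def test_specificity_ordering_comp_beats_group(lib):
    args = ("LYS", ChemGroup.PEPTIDE, "PRO", ChemGroup.P_PEPTIDE)
    scores = {lid: score_specificity(lib.links[lid], *args)[0]
              for lid in ("LYS-PRO", "PEPT-PRO", "PTRANS")}
    assert scores == {"LYS-PRO": 4, "PEPT-PRO": 3, "PTRANS": 2}
    assert scores["LYS-PRO"] > scores["PEPT-PRO"] > scores["PTRANS"]


def test_specificity_via_alias_group(lib):
    cir = lib.monomer("CIR")
    sc = score_specificity(lib.links["TRANS"], "CIR", cir.group, "ALA",
                           ChemGroup.PEPTIDE,
                           alias_group1=cir.alias.group_context)
    assert sc is not None and sc[0] == 2


def test_incompatible_groups_do_not_match(lib):
    assert score_specificity(lib.links["TRANS"], "DA", ChemGroup.DNA, "ALA",
                             ChemGroup.PEPTIDE) is None
    assert score_specificity(lib.links["NUC"], "DA", ChemGroup.DNA, "ALA",
                             ChemGroup.PEPTIDE) is None


@pytest.mark.parametrize("omega, expected", [(178.0, "TRANS"), (2.0, "CIS")])
def test_cis_trans_disambiguation_matches_periodic_distance_oracle(
        lib, pipeline, omega, expected):
    model = fixtures.build_peptide_model(["ALA", "ALA"], omegas=[omega],
                                         noise=0.0)
    _, _, matches, _ = pipeline(model, lib)
    assert [m.link.link_id for m in matches] == [expected]
    # independent oracle: measured omega against the two ideals
    r1, r2 = model.chains[0].residues
    w = torsion_deg(r1.get_atom("CA").position, r1.get_atom("C").position,
                    r2.get_atom("N").position, r2.get_atom("CA").position)
    closest = min((abs(periodic_delta(w, ideal)), name)
                  for ideal, name in ((180.0, "TRANS"), (0.0, "CIS")))[1]
    assert closest == expected


def test_exact_tie_breaks_lexicographically_with_warning(lib, pipeline, caplog):
    model = fixtures.build_peptide_model(["ALA", "ALA"], omegas=[90.0],
                                         noise=0.0)
    import logging
    logging.getLogger("restraintsmith.linkage").setLevel(logging.WARNING)
    with caplog.at_level("WARNING", logger="restraintsmith.linkage"):
        _, _, matches, _ = pipeline(model, lib)
    assert matches[0].link.link_id == "CIS"  # CIS < TRANS
    assert any("tie" in rec.message for rec in caplog.records)


def test_ssbond_record_matches_ss_link(lib, pipeline):
    model = fixtures.make_toy_model({"kind": "disulfide", "noise": 0.0})
    _, _, matches, _ = pipeline(model, lib)
    assert [m.link.link_id for m in matches] == ["SS"]


def test_link_without_description_falls_back_to_bond_only(lib, pipeline):
    model = fixtures.make_toy_model({"kind": "odd_link", "noise": 0.0})
    _, _, matches, rset = pipeline(model, lib)
    assert len(matches) == 1 and matches[0].fallback
    fallback = [r for r in rset if r.provenance == "fallback"]
    assert len(fallback) == 1 and fallback[0].kind == "bond"


def test_unknown_named_link_lists_known_ids(lib, pipeline):
    model = fixtures.make_toy_model(
        {"kind": "peptide", "sequence": ["ALA", "ALA"], "noise": 0.0,
         "conn": [{"kind": "LINKR", "seq1": 1, "atom1": "C", "seq2": 2,
                   "atom2": "N", "link_id": "NOSUCH"}]})
    with pytest.raises(LinkIdentificationError, match="TRANS"):
        pipeline(model, lib)


def test_microheterogeneity_shared_atom_gives_two_matches(lib, pipeline):
    model = fixtures.make_toy_model({"kind": "microheterogeneity",
                                     "noise": 0.0})
    _, _, matches, _ = pipeline(model, lib)
    assert len(matches) == 2
    comps = sorted(m.side2_ctx.residue.comp_id for m in matches)
    assert comps == ["ALA", "GLY"]


def test_altloc_pair_cis_and_trans_links(lib, pipeline):
    model = fixtures.make_toy_model({"kind": "cis_trans_altloc", "noise": 0.0})
    _, _, matches, _ = pipeline(model, lib)
    by_alt = {m.altlocs[1]: m.link.link_id for m in matches}
    assert by_alt == {"A": "TRANS", "B": "CIS"}


def test_partial_cleavage_links_only_one_conformer(lib, pipeline):
    model = fixtures.make_toy_model({"kind": "partial_cleavage", "noise": 0.0})
    _, _, matches, _ = pipeline(model, lib)
    assert [m.altlocs for m in matches] == [("", "A")]


def test_match_list_independent_of_dictionary_order(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
    _, _, m1, _ = pipeline(model, lib)
    import copy
    shuffled = copy.copy(lib)
    shuffled.links = dict(reversed(list(lib.links.items())))
    model2 = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
    _, _, m2, _ = pipeline(model2, shuffled)
    assert [(x.link.link_id, x.altlocs) for x in m1] == \
        [(x.link.link_id, x.altlocs) for x in m2]


def test_alias_equivalence_of_match_sets(lib, lib_renamed, pipeline):
    """Headline property: nonstandard names + alias produce the same links
    as the same model renamed to standard nomenclature."""
    aliased = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
    renamed = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0,
                                           cir_names="standard")
    _, _, ma, _ = pipeline(aliased, lib)
    _, _, mr, _ = pipeline(renamed, lib_renamed)
    sig = lambda ms: [(m.link.link_id, m.specificity, m.orientation,
                       m.altlocs) for m in ms]
    assert sig(ma) == sig(mr)


def test_missing_monomer_error_names_it(lib):
    model = fixtures.build_peptide_model(["ALA"], noise=0.0)
    model.chains[0].residues[0].comp_id = "UNK"
    with pytest.raises(SchemaError, match="UNK"):
        resolve_model(model, lib)


def test_auto_detection_finds_unannotated_bond(lib, pipeline):
    model = fixtures.make_toy_model({"kind": "odd_link", "noise": 0.0})
    model.conn = []  # drop the LINK record; only the distance remains
    opts = Options(auto_links=True)
    _, cands, _, _ = pipeline(model, lib, opts)
    assert any(c.origin == "distance_search" for c in cands)
    # and the default leaves it off
    _, cands_default, _, _ = pipeline(model, lib)
    assert not any(c.origin == "distance_search" for c in cands_default)
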
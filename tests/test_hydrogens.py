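"""Riding-hydrogen placement: exactness, ambiguity, symmetry, determinism."""

import numpy as np
import pytest

from restraintsmith import fixtures
from restraintsmith._geom import angle_deg, random_rotation
from restraintsmith.hydrogens import (
    HPlacementProblem,
    classify_site,
    nucleus_cloud_switch,
    place_hydrogens,
    solve_problem,
)
from restraintsmith.linkage import find_bond_candidates, match_links, resolve_model
from restraintsmith.restraints import RestraintSet, build_restraints


def _prep(model, lib):
    ctx = resolve_model(model, lib)
    cands = find_bond_candidates(model, lib, contexts=ctx)
    matches = match_links(cands, lib, model)
    return ctx, matches


def _h_distance_errors(model, lib):
    errs = []
    for chain in model.chains:
        for r in chain.residues:
            d = lib.monomer(r.comp_id)
            for a in r.atoms:
                if a.element != "H":
                    continue
                parent = [n for n in d.bonded_to(a.name)
                          if not d.get_atom(n).is_hydrogen][0]
                ideal = d.bond_between(parent, a.name).ideal
                got = np.linalg.norm(a.position - r.get_atom(parent).position)
                errs.append(abs(got - ideal))
    return errs


def test_placed_hydrogens_at_exact_ideal_distance(lib):
    model = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
    ctx, matches = _prep(model, lib)
    place_hydrogens(model, lib, matches, contexts=ctx)
    errs = _h_distance_errors(model, lib)
    assert errs and max(errs) <= 1e-6


def test_case_taxonomy(lib):
    model = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
    ctx, matches = _prep(model, lib)
    report = place_hydrogens(model, lib, matches, contexts=ctx)
    by_atom = {(e["seq_id"], e["atom"]): e["case"] for e in report}
    assert by_atom[(1, "HA")] == "three_neighbors"       # N, C, CB known
    assert by_atom[(1, "H")] == "one_neighbor_with_torsion"  # NH3 rotor
    assert by_atom[(2, "HN1")] == "two_neighbors"        # amide H


def test_hydroxyl_type_hydrogen_gets_zero_occupancy(lib):
    model = fixtures.build_peptide_model(["CYS"], noise=0.0)
    ctx, matches = _prep(model, lib)
    report = place_hydrogens(model, lib, matches, contexts=ctx)
    hg = model.chains[0].residues[0].get_atom("HG")
    assert hg is not None and hg.occupancy == 0.0
    entry = next(e for e in report if e["atom"] == "HG")
    assert entry["case"] == "one_neighbor_free" and entry["ambiguous"]


def test_unknown_protonation_marker_forces_zero_occupancy(lib, tmp_path):
    """A dictionary may flag specific hydrogens as protonation-ambiguous;
    those are placed but at occupancy zero, like unresolved tautomers."""
    from restraintsmith.monomer_library import MonomerLibrary, monomer_to_cif
    d = lib.monomer("ALA").copy()
    d.ambiguous_h = {"HB1", "HB2", "HB3"}
    lib2 = MonomerLibrary()
    lib2.add_document(monomer_to_cif(d))
    lib2.links.update(lib.links)
    lib2.mods.update(lib.mods)
    assert lib2.monomer("ALA").ambiguous_h == {"HB1", "HB2", "HB3"}
    model = fixtures.build_peptide_model(["ALA"], noise=0.0)
    ctx, matches = _prep(model, lib2)
    place_hydrogens(model, lib2, matches, contexts=ctx)
    res = model.chains[0].residues[0]
    assert all(res.get_atom(h).occupancy == 0.0
               for h in ("HB1", "HB2", "HB3"))


def test_unsolvable_isolated_atom_reported_not_added():
    problem = HPlacementProblem(
        parent_name="O", parent_pos=np.zeros(3), h_name="H",
        distance=0.86, known_neighbors=[],
    )
    assert classify_site(problem) == "unsolvable"
    pos, ambiguous = solve_problem(problem)
    assert pos is None


def test_angles_near_least_squares_optimum(lib):
    """For the sp3 CA-H with three known neighbors the angle residuals
    split the over-determination evenly."""
    model = fixtures.build_peptide_model(["ALA"], noise=0.0)
    ctx, matches = _prep(model, lib)
    place_hydrogens(model, lib, matches, contexts=ctx)
    r = model.chains[0].residues[0]
    p = lambda n: r.get_atom(n).position
    d = lib.monomer("ALA")
    resid = []
    for t in d.templates_of("angle"):
        if "HA" not in t.atom_names:
            continue
        a, b, c = t.atom_names
        resid.append((angle_deg(p(a), p(b), p(c)) - t.ideal) / t.sigma)
    # perturbing the placed direction must not improve the LS objective
    base = sum(z * z for z in resid)
    ha = r.get_atom("HA")
    ca = p("CA")
    rng = np.random.default_rng(0)
    for _ in range(20):
        u = ha.position - ca
        v = u + rng.normal(0, 1e-3, 3)
        v = v / np.linalg.norm(v) * np.linalg.norm(u)
        trial = 0.0
        for t in d.templates_of("angle"):
            if "HA" not in t.atom_names:
                continue
            a, b, c = t.atom_names
            pa = ca + v if a == "HA" else p(a)
            pc = ca + v if c == "HA" else p(c)
            trial += ((angle_deg(pa, p(b), pc) - t.ideal) / t.sigma) ** 2
        assert trial >= base - 1e-6


def test_two_neighbor_chirality_sign_selects_mirror_slot():
    """With two known neighbors there are two mirror solutions; the
    chirality sign picks the side, and flipping the sign gives the exact
    reflection through the neighbor plane."""
    parent = np.zeros(3)
    n1 = np.array([1.5, 0.0, 0.0])
    n2 = np.array([-0.5, 1.4, 0.0])
    positions = {}
    for sign in ("positive", "negative"):
        problem = HPlacementProblem(
            parent_name="CB", parent_pos=parent, h_name="HB",
            distance=0.97,
            known_neighbors=[("CA", n1), ("SG", n2)],
            angle_constraints=[(n1, 109.5, 1.5), (n2, 109.5, 1.5)],
            chirality=(n1, n2, sign),
        )
        assert classify_site(problem) == "two_neighbors"
        pos, ambiguous = solve_problem(problem)
        assert not ambiguous
        positions[sign] = pos
    # the neighbor plane is z = 0: the two assignments are reflections
    flip = np.array([1.0, 1.0, -1.0])
    assert np.allclose(positions["positive"], positions["negative"] * flip,
                       atol=1e-6)
    assert positions["positive"][2] > 0 > positions["negative"][2]


def test_methylene_pair_lies_on_opposite_sides(lib):
    """The two glycine alpha hydrogens straddle the N/CA/C plane."""
    model = fixtures.build_peptide_model(["GLY"], noise=0.0)
    ctx, matches = _prep(model, lib)
    place_hydrogens(model, lib, matches, contexts=ctx)
    r = model.chains[0].residues[0]
    from restraintsmith._geom import chiral_volume
    ca = r.get_atom("CA").position
    v2 = chiral_volume(ca, r.get_atom("N").position,
                       r.get_atom("C").position, r.get_atom("HA2").position)
    v3 = chiral_volume(ca, r.get_atom("N").position,
                       r.get_atom("C").position, r.get_atom("HA3").position)
    assert v2 * v3 < 0


def test_rigid_motion_equivariance(lib):
    base = fixtures.build_peptide_model(["ALA", "ALA"], noise=0.0)
    ctx, matches = _prep(base, lib)
    place_hydrogens(base, lib, matches, contexts=ctx)
    ref = {(r.seq_id, a.name): a.position.copy()
           for _, r, a in base.all_atoms()}
    rng = np.random.default_rng(42)
    for _ in range(10):
        R = random_rotation(rng)
        t = rng.normal(0, 5, 3)
        model = fixtures.build_peptide_model(["ALA", "ALA"], noise=0.0)
        for _, _, a in model.all_atoms():
            a.position = R @ a.position + t
        ctx2, matches2 = _prep(model, lib)
        place_hydrogens(model, lib, matches2, contexts=ctx2)
        for _, r, a in model.all_atoms():
            expected = R @ ref[(r.seq_id, a.name)] + t
            assert np.linalg.norm(a.position - expected) < 1e-6


def test_determinism_bit_identical(lib):
    runs = []
    for _ in range(2):
        model = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.0)
        ctx, matches = _prep(model, lib)
        place_hydrogens(model, lib, matches, contexts=ctx)
        runs.append([(r.seq_id, a.name, a.position.tobytes())
                     for _, r, a in model.all_atoms()])
    assert runs[0] == runs[1]


def test_keep_mode_preserves_existing_hydrogens(lib):
    model = fixtures.build_peptide_model(["ALA"], noise=0.0)
    ctx, matches = _prep(model, lib)
    place_hydrogens(model, lib, matches, contexts=ctx)
    r = model.chains[0].residues[0]
    marker = np.array([99.0, 99.0, 99.0])
    r.get_atom("HA").position = marker.copy()
    place_hydrogens(model, lib, matches, regenerate=False, contexts=ctx)
    assert np.array_equal(r.get_atom("HA").position, marker)
    place_hydrogens(model, lib, matches, regenerate=True, contexts=ctx)
    assert not np.array_equal(r.get_atom("HA").position, marker)


def test_nucleus_vs_cloud_distance_selection(lib):
    by_mode = {}
    for mode in ("electron_cloud", "nucleus"):
        model = fixtures.build_peptide_model(["ALA"], noise=0.0)
        ctx, matches = _prep(model, lib)
        place_hydrogens(model, lib, matches, distance_mode=mode, contexts=ctx)
        r = model.chains[0].residues[0]
        by_mode[mode] = float(np.linalg.norm(
            r.get_atom("H").position - r.get_atom("N").position))
    assert by_mode["electron_cloud"] == pytest.approx(0.86, abs=1e-9)
    assert by_mode["nucleus"] == pytest.approx(1.02, abs=1e-9)


def test_nucleus_cloud_switch_on_restraint_sets(lib):
    model = fixtures.build_peptide_model(["ALA"], noise=0.0)
    ctx, matches = _prep(model, lib)
    place_hydrogens(model, lib, matches, contexts=ctx)
    rset = build_restraints(model, lib, matches, contexts=ctx)
    nuc = nucleus_cloud_switch(rset, "nucleus")
    nh = [(r.ideal, r.ideal_nucleus) for r in nuc.of_kind("bond")
          if {a.name for a in r.atoms} == {"N", "H"}][0]
    assert nh[0] == 1.02
    cloud = nucleus_cloud_switch(rset, "electron_cloud")
    nh2 = [r.ideal for r in cloud.of_kind("bond")
           if {a.name for a in r.atoms} == {"N", "H"}][0]
    assert nh2 == 0.86
    # single-ideal bonds are identical in both modes
    heavy = [r.ideal for r in nuc.of_kind("bond")
             if {a.name for a in r.atoms} == {"CA", "C"}][0]
    assert heavy == 1.525
    assert len(nucleus_cloud_switch(RestraintSet(), "nucleus")) == 0
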
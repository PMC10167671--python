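"""Geometry target evaluation and minimization."""

import numpy as np
import pytest

from restraintsmith import fixtures
from restraintsmith._geom import angle_deg, random_rotation
from restraintsmith.config import Options
from restraintsmith.model_io import AtomSite, Chain, Residue, StructureModel
from restraintsmith.regularize import (
    GeometryTarget,
    build_target,
    evaluate,
    minimize,
)
from restraintsmith.restraints import AtomRef, Restraint, RestraintSet


def _two_atom_target(distance):
    a1 = AtomSite(name="C1", element="C", position=np.zeros(3))
    a2 = AtomSite(name="C2", element="C",
                  position=np.array([distance, 0.0, 0.0]))
    res = Residue(seq_id=1, comp_id="XXX", atoms=[a1, a2])
    model = StructureModel(chains=[Chain("A", [res])])
    ref1 = AtomRef("A", 1, "", "XXX", "C1", "", a1)
    ref2 = AtomRef("A", 1, "", "XXX", "C2", "", a2)
    rset = RestraintSet([Restraint("bond", (ref1, ref2), 1.0, 0.02)])
    return GeometryTarget(model=model, rset=rset, repulsion=False)


def test_single_stretched_bond_closed_form():
    t = _two_atom_target(1.1)
    value, grad = evaluate(t, t.coords())
    assert value == pytest.approx(25.0)     # (0.1 / 0.02)^2
    t0 = _two_atom_target(1.0)
    v0, g0 = evaluate(t0, t0.coords())
    assert v0 == 0.0 and np.allclose(g0, 0.0)


def test_gradient_matches_finite_differences(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "ALA"], noise=0.1, seed=3)
    _, _, _, rset = pipeline(model, lib, hydrogens=True)
    t = build_target(model, rset, Options())
    x = t.coords()
    _, g = evaluate(t, x)
    rng = np.random.default_rng(0)
    for _ in range(40):
        i = int(rng.integers(len(x)))
        j = int(rng.integers(3))
        h = 1e-6
        xp = x.copy(); xp[i, j] += h
        xm = x.copy(); xm[i, j] -= h
        fd = (evaluate(t, xp)[0] - evaluate(t, xm)[0]) / (2 * h)
        assert abs(fd - g[i, j]) / max(1.0, abs(fd)) < 1e-5


def test_value_invariant_under_rigid_motions(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.1,
                                         seed=7)
    _, _, _, rset = pipeline(model, lib)
    t = build_target(model, rset, Options())
    x = t.coords()
    v0, _ = evaluate(t, x)
    rng = np.random.default_rng(11)
    for _ in range(10):
        R = random_rotation(rng)
        shift = rng.normal(0, 10, 3)
        v, _ = evaluate(t, x @ R.T + shift)
        assert v == pytest.approx(v0, rel=1e-9)


def test_missing_coordinates_raise(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA"], noise=0.0)
    _, _, _, rset = pipeline(model, lib)
    t = build_target(model, rset, Options())
    with pytest.raises(Exception, match="non-finite"):
        bad = t.coords()
        bad[0, 0] = np.nan
        evaluate(t, bad)


def test_zero_cycles_is_identity(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "ALA"], noise=0.1, seed=5)
    _, _, _, rset = pipeline(model, lib)
    t = build_target(model, rset, Options())
    x = t.coords()
    res = minimize(t, cycles=0)
    assert np.array_equal(res.coords, x)
    assert len(res.trajectory) == 1


def test_monotone_descent_over_20_cycles(lib, pipeline):
    model = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.15,
                                         seed=1)
    _, _, _, rset = pipeline(model, lib, hydrogens=True)
    t = build_target(model, rset, Options())
    res = minimize(t, cycles=20)
    traj = res.trajectory
    assert all(a >= b - 1e-12 for a, b in zip(traj, traj[1:]))
    assert traj[-1] < traj[0]


def test_alias_run_restores_link_angles(lib, pipeline):
    """20 cycles on the perturbed nonstandard-monomer fixture bring the
    inter-residue angles back to their link ideals."""
    model = fixtures.build_peptide_model(["ALA", "CIR", "ALA"], noise=0.15,
                                         seed=1)
    _, _, _, rset = pipeline(model, lib, hydrogens=True)
    t = build_target(model, rset, Options())
    res = minimize(t, cycles=20)
    assert res.rms_after["angle/link"] < 1.0
    t.set_coords(res.coords)
    r1, r2, _ = model.chains[0].residues
    p = lambda r, n: r.get_atom(n).position
    assert abs(angle_deg(p(r1, "CA"), p(r1, "C"), p(r2, "N1")) - 115.9) < 1.0
    assert abs(angle_deg(p(r1, "C"), p(r2, "N1"), p(r2, "C2")) - 122.1) < 1.0


def test_without_alias_no_link_angle_terms(lib_noalias, pipeline):
    """Dropping the alias leaves the junction angles unconstrained: the
    target contains no link angle terms at all."""
    model = fixtures.make_toy_model(
        {"kind": "peptide", "sequence": ["ALA", "CIR", "ALA"], "noise": 0.15,
         "conn": [{"seq1": 1, "atom1": "C", "seq2": 2, "atom2": "N"},
                  {"seq1": 2, "atom1": "C", "seq2": 3, "atom2": "N"}]},
        seed=1)
    _, _, _, rset = pipeline(model, lib_noalias)
    t = build_target(model, rset, Options())
    res = minimize(t, cycles=20)
    assert "angle/link" not in res.rms_after
    assert all(r.kind == "bond" for r in rset
               if r.provenance_class() in ("link", "fallback"))


def test_zero_occupancy_hydrogens_do_not_move(lib, pipeline):
    model = fixtures.build_peptide_model(["CYS"], noise=0.05, seed=2)
    _, _, _, rset = pipeline(model, lib, hydrogens=True)
    t = build_target(model, rset, Options())
    hg_index = next(i for i, a in enumerate(t.atoms) if a.name == "HG")
    assert not t.moving_mask[hg_index]
    before = t.coords()[hg_index].copy()
    res = minimize(t, cycles=10)
    assert np.array_equal(res.coords[hg_index], before)
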
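import logging

import pytest

from restraintsmith import fixtures
from restraintsmith.config import Options
from restraintsmith.hydrogens import place_hydrogens
from restraintsmith.linkage import find_bond_candidates, match_links, resolve_model
from restraintsmith.monomer_library import MonomerLibrary
from restraintsmith.restraints import build_restraints

logging.getLogger("restraintsmith").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def lib_dir(tmp_path_factory):
    return fixtures.make_mini_library(tmp_path_factory.mktemp("minilib"))


@pytest.fixture(scope="session")
def lib(lib_dir):
    return MonomerLibrary.load(lib_dir)


@pytest.fixture(scope="session")
def lib_renamed(tmp_path_factory):
    root = fixtures.make_mini_library(
        tmp_path_factory.mktemp("minilib_renamed"),
        cir_variant="renamed", orx_variant="renamed",
    )
    return MonomerLibrary.load(root)


@pytest.fixture(scope="session")
def lib_noalias(tmp_path_factory):
    root = fixtures.make_mini_library(
        tmp_path_factory.mktemp("minilib_noalias"),
        cir_variant="noalias", orx_variant="noalias",
    )
    return MonomerLibrary.load(root)


def run_parts(model, lib, options=None, hydrogens=False):
    """Resolve, identify links, optionally add H, build restraints."""
    options = options or Options()
    contexts = resolve_model(model, lib)
    candidates = find_bond_candidates(model, lib, options, contexts)
    matches = match_links(candidates, lib, model, options)
    if hydrogens:
        place_hydrogens(model, lib, matches, contexts=contexts,
                        distance_mode=options.h_distance_mode)
    rset = build_restraints(model, lib, matches, options, contexts)
    return contexts, candidates, matches, rset


@pytest.fixture(scope="session")
def pipeline():
    return run_parts
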
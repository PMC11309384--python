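import os

import numpy as np
import pytest

from ribannot import fixtures
from ribannot.chaintypes import ComponentInfo


@pytest.fixture(scope="session")
def duplex8():
    """8-bp GC duplex with ground truth (zero jitter)."""
    return fixtures.make_duplex(fixtures.HelixSpec("GGGGCCCC"))


@pytest.fixture(scope="session")
def hairpin():
    """Stem-6/loop-4 hairpin with ground truth."""
    return fixtures.make_hairpin(6, 4)


@pytest.fixture(scope="session")
def hairpin_mg():
    """Hairpin with an Mg ion placed 2.1 A from residues 4 and 5."""
    hp, truth = fixtures.make_hairpin(6, 4, entry_id="fmg")
    st = fixtures.place_ligand(
        hp, [("A", 4, "O2"), ("A", 5, "N9")], 2.1,
        ComponentInfo("MG", {"Mg": 1}))
    return st, truth


@pytest.fixture(scope="session")
def u2_cif(tmp_path_factory):
    """Synthetic stand-in for the 1a9n chain/assembly layout, on disk."""
    path = tmp_path_factory.mktemp("u2") / "u2_like.cif"
    fixtures.write_mmcif(fixtures.make_u2_snrnp_like(), path)
    return str(path)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Fixture bundle (structures + toy mapping tables + manifest)."""
    outdir = tmp_path_factory.mktemp("bundle")
    return fixtures.make_fixture_bundle(str(outdir))
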
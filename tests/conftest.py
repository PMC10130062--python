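"""Shared fixtures: all test structures are generated synthetically."""

import numpy as np
import pytest

from minimet import fixtures, loop_closure, miniaturizer


@pytest.fixture(scope="session")
def template():
    """Synthetic rubredoxin-like template with a pseudo-C2 (0.05 A jitter)."""
    return fixtures.make_synthetic_template(seed=1, jitter=0.05)


@pytest.fixture(scope="session")
def c2_axis(template):
    half_a = miniaturizer.dissect(template, "A", 6, 10)
    half_b = miniaturizer.dissect(template, "A", 39, 43)
    return miniaturizer.fit_c2_axis(half_a, half_b)


@pytest.fixture(scope="session")
def dimer(template, c2_axis):
    frag = miniaturizer.dissect(template, "A", 38, 50)
    metal = template.get_residue("A", 60).atoms[0]
    return miniaturizer.make_c2_dimer(frag, c2_axis, metal=metal)


@pytest.fixture(scope="session")
def dimer_stubs(dimer):
    return loop_closure.extract_stubs(dimer)


@pytest.fixture(scope="session")
def planted_library(tmp_path_factory):
    """Mini-library with planted 3-, 4- and 5-residue loops plus decoys."""
    out = tmp_path_factory.mktemp("library")
    lib, planted = fixtures.make_mini_library(
        out,
        n_structures=12,
        planted_loops=[(4, "I'"), (3, None), (5, None)],
        seed=0,
        loop_sequences=["GGGG", "AGA", "AGGKA"],
    )
    return lib, planted


@pytest.fixture(scope="session")
def ideal_site():
    return fixtures.make_ideal_site()


@pytest.fixture(scope="session")
def design_pair():
    return fixtures.make_synthetic_design_pair(seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
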
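import numpy as np
import pytest

import twobead as tb
from twobead.fixtures import FixtureSpec, dock_peptide, make_fixture
from twobead.sidechain import ThreadingConfig


@pytest.fixture(scope="session")
def params():
    return tb.default_params()


@pytest.fixture(scope="session")
def helix():
    return make_fixture(FixtureSpec("ideal_helix", 20, seed=1))


@pytest.fixture(scope="session")
def sheet():
    return make_fixture(FixtureSpec("ideal_sheet", 20, seed=1))


@pytest.fixture(scope="session")
def coil():
    return make_fixture(FixtureSpec("coil", 20, seed=2))


@pytest.fixture(scope="session")
def fold():
    """Compact designed two-domain fold used across the suite."""
    return make_fixture(FixtureSpec("two_domain_fold", 30, seed=2))


@pytest.fixture(scope="session")
def complex_pair():
    """Helix receptor + extended peptide with a hydrophobic interface."""
    return make_fixture(FixtureSpec("toy_complex", 24, seed=4))


@pytest.fixture(scope="session")
def docked(fold):
    """(fold, peptide) with the peptide docked against the fold surface."""
    return fold, dock_peptide(fold)


@pytest.fixture(scope="session")
def fast_thread():
    """Reduced threading settings for test-scale workloads."""
    return ThreadingConfig(n_steps=5, seed=11, final_grid=24)


def random_structure(n, seed, params):
    """Small random coil with a random (G-containing) sequence, for oracles."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(tb.AMINO_ACIDS))
    seq = "".join(letters[rng.integers(0, 20, size=n)])
    spec = FixtureSpec("coil", n, seed=seed + 1)
    trace = make_fixture(spec)
    from twobead.sidechain import thread

    return thread(seq, trace, ThreadingConfig(n_steps=3, seed=seed), params)
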
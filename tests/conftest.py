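import numpy as np
import pytest

from teleotd import synthetic_data as sd
from teleotd.prset_distance import (
    load_substitution_matrix,
    rescale_substitution_matrix,
)


@pytest.fixture(scope="session")
def td_mixture():
    return sd.teleost_mixture()


@pytest.fixture(scope="session")
def vert_mixture():
    return sd.vertebrate_mixture()


@pytest.fixture(scope="session")
def blosum62():
    return load_substitution_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def residue_distance(blosum62):
    return rescale_substitution_matrix(blosum62)


@pytest.fixture()
def fixture_tree():
    return sd.teleost_fixtures()


@pytest.fixture(scope="session")
def akrab_family():
    """A consensus, its profile alignment rows, and proteins carrying it."""
    rng = np.random.default_rng(42)
    cons = "".join(rng.choice(list(sd.AMINO_ACIDS), size=60))
    aa = np.array(list(sd.AMINO_ACIDS))
    rows = []
    for i in range(12):
        s = np.array(list(cons))
        for j in np.flatnonzero(rng.random(60) < 0.05):
            s[j] = rng.choice(aa[aa != s[j]])
        rows.append((f"row{i:02d}", "".join(s)))
    return cons, rows
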
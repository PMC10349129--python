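import numpy as np
import pytest

from hismethyl import chem


@pytest.fixture(scope="session")
def mod_table():
    return chem.default_modification_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230714)


def random_peptide(rng, min_len=5, max_len=20, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(alphabet), n))
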
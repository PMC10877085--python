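import numpy as np
import pytest
from hypothesis import settings

from fgf21stab import datasets
from fgf21stab import synthetic as syn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: planted column compositions mirroring the evolution-arm rows of the
#: published mutation table: M at 47/58 (0.81), K at 29/58 (0.50),
#: R at 30/58 (0.52)
PLANTED_COLUMNS = [
    syn.ColumnSpec(104, {"M": 47, "Q": 5, "V": 3, "I": 2, "L": 1}),
    syn.ColumnSpec(
        139, {"K": 29, "A": 10, "R": 6, "Q": 4, "L": 3, "N": 2, "T": 2, "G": 1, "H": 1}
    ),
    syn.ColumnSpec(
        150,
        {"R": 30, "K": 15, "Q": 3, "D": 2, "P": 2, "N": 1, "T": 1, "A": 1, "S": 1,
         "E": 1, "G": 1},
    ),
]


@pytest.fixture(scope="session")
def wt_precursor() -> str:
    return datasets.wild_type_precursor()


@pytest.fixture(scope="session")
def planted_alignment(wt_precursor):
    """58-deep alignment with the three consensus columns planted exactly."""
    return syn.gen_alignment(PLANTED_COLUMNS, depth=58, seed=11, query_seq=wt_precursor)


@pytest.fixture(scope="session")
def single_variants():
    return datasets.single_mutant_variants()


@pytest.fixture(scope="session")
def multi_variants():
    return datasets.multi_mutant_variants()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
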
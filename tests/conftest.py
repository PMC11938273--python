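import numpy as np
import pytest

from bbbperm import molio, synthdata


@pytest.fixture(scope="session")
def fixture_molecules():
    """The five packaged molecules, annotated with Bondi radii."""
    return {
        name: molio.assign_vdw_radii(mol)
        for name, mol in synthdata.fixture_molecules().items()
    }


@pytest.fixture(scope="session")
def default_table():
    """One default synthetic feature table (154 rows, 68/42/44)."""
    return synthdata.generate_feature_table(seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
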
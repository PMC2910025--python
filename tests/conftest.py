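import numpy as np
import pytest

from kinopcm import SyntheticConfig, generate_dataset
from kinopcm.descriptors import describe_set
from kinopcm.preprocessing import DesignBuilder


@pytest.fixture(scope="session")
def small_panel():
    """A small but structured panel: 40 kinases x 12 inhibitors."""
    return generate_dataset(SyntheticConfig(n_kinases=40, n_inhibitors=12, seed=11))


@pytest.fixture(scope="session")
def small_builder(small_panel):
    kin = describe_set(small_panel.msa, "aligned_z")
    return DesignBuilder(small_panel.ligand_table, kin, small_panel.activity)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_sequence(rng, n):
    from kinopcm.tables import AMINO_ACIDS
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, n)])
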
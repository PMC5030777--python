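import numpy as np
import pandas as pd
import pytest

from srnakit.io_formats import TagTable
from srnakit.synthetic import SimConfig, gen_mirna_locus


@pytest.fixture
def two_lib_table() -> TagTable:
    return TagTable.from_rows(
        [
            ("ACGTACGTACGTACGTACGT", {"lib1": 5, "lib2": 0}),
            ("TTTTACGTACGTACGTACGTACG", {"lib1": 2, "lib2": 3}),
        ],
        ["lib1", "lib2"],
    )


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def canonical_locus(sim_config):
    """A 5p hairpin locus passing every structural criterion."""
    return gen_mirna_locus(sim_config, arm="5p", seed=7, name="locusA")


def make_matrix(values: dict[str, list[float]], genes: list[str]) -> pd.DataFrame:
    return pd.DataFrame(values, index=genes, dtype="float64")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
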
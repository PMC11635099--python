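import numpy as np
import pytest

from denovopool import GrowthSimConfig, LibraryDesign, generate_library


@pytest.fixture(scope="session")
def design():
    return LibraryDesign()


@pytest.fixture(scope="session")
def big_library(design):
    """Unbiased library of 1e5 clones, shared by the statistical tests."""
    return generate_library(100_000, design=design, seed=20240)


@pytest.fixture(scope="session")
def small_library(design):
    return generate_library(40, design=design, seed=7)


@pytest.fixture
def tiny_config():
    return GrowthSimConfig(
        n_replicates=2,
        n_timepoints=3,
        cells_per_passage=20_000,
        read_depth=5_000,
        error_rate=0.0,
    )
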
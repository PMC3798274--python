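import numpy as np
import pandas as pd
import pytest

from taxadecon import simulator


@pytest.fixture(scope="session")
def small_community():
    """12 model species over a 30-gene catalog (incl. the constant gene)."""
    return simulator.simulate_genomes(12, 30, seed=42)


@pytest.fixture(scope="session")
def small_profiles(small_community):
    return simulator.simulate_abundance_profiles(small_community, 25, 0.3, seed=7)


@pytest.fixture(scope="session")
def small_sampleset(small_community, small_profiles):
    return simulator.simulate_metagenomes(
        small_community, small_profiles, 1_000_000, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def toy_profile():
    return pd.DataFrame(
        [[0.5, 0.5], [0.8, 0.2], [1.0, 0.0]],
        index=["S1", "S2", "S3"],
        columns=["taxA", "taxB"],
    )
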
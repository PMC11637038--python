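import numpy as np
import pytest

import nicuq


@pytest.fixture(scope="session")
def table() -> nicuq.RateTable:
    """The packaged per-infant rate table from the field study."""
    return nicuq.load_reference_rates()


@pytest.fixture(scope="session")
def dist() -> nicuq.MixDistribution:
    """The synthetic-plausible mix distribution of a busy 11-13 bed unit."""
    return nicuq.default_mix_distribution()


@pytest.fixture()
def config() -> nicuq.PolicyConfig:
    return nicuq.PolicyConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150611)
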
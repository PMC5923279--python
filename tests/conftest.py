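import numpy as np
import pytest

from metadigest.simulate import SyntheticConfig, generate_dataset

#: study conditions restricted to the serum compartment (64 buckets,
#: 8 informative) — the workhorse configuration for simulation tests
SERUM_ONLY = dict(n_buckets={"serum": 64}, n_informative={"serum": 8})


@pytest.fixture(scope="session")
def serum_dataset():
    """One planted serum cohort at the default study conditions."""
    return generate_dataset(SyntheticConfig(seed=1, **SERUM_ONLY))


@pytest.fixture(scope="session")
def full_dataset():
    """All three compartments at default study conditions."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_serum(seed: int, **overrides):
    cfg = {**SERUM_ONLY, **overrides}
    return generate_dataset(SyntheticConfig(seed=seed, **cfg))
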
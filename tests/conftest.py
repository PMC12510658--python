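import numpy as np
import pytest

import ppiflux as px


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Replicate dataset whose replicates equal the anchor-derived means."""
    return px.generate(noise=px.NoiseModel(cv=0.0))


@pytest.fixture(scope="session")
def noisy_dataset():
    return px.generate(noise=px.NoiseModel(cv=0.2, seed=11))


def random_params(spec, rng, lo=-4.0, hi=2.0):
    """One random draw from the prior box, linear scale."""
    return {n: 10.0 ** rng.uniform(lo, hi) for n in spec.free_parameter_names}
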
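import numpy as np
import pytest

import commocc as co


@pytest.fixture(scope="session")
def reduced_dataset():
    """One reduced-scale synthetic survey with known truth."""
    cfg = co.reduced_scale(seed=5)
    sites, truth, data, traits = co.generate_dataset(cfg)
    return cfg, sites, truth, data, traits


@pytest.fixture(scope="session")
def reduced_model_data(reduced_dataset):
    _, sites, truth, data, traits = reduced_dataset
    return co.prepare_model_data(co.augment(data, 40), traits)


@pytest.fixture(scope="session")
def reduced_fit(reduced_model_data):
    """Two-chain fit of the reduced synthetic survey, shared across tests."""
    mc = co.McmcConfig(n_iter=9_000, burn_in=3_000, thin=5, n_chains=2, seed=2)
    return co.run_chains(reduced_model_data, co.PriorSpec(), mc)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
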
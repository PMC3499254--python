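import numpy as np
import pandas as pd
import pytest

import popglm as pg


@pytest.fixture(scope="session")
def cosine_population():
    """Small conditionally independent cosine-tuned population."""
    spec = pg.PopulationSpec(
        n_neurons=6, n_trials=1600, bin_duration=0.2, tuning_kind="cosine",
        seed=101,
    )
    counts, cov = pg.simulate_tuned_population(spec)
    return spec, counts, cov


@pytest.fixture(scope="session")
def chain_data():
    """Three-neuron feed-forward chain (only neuron 0 truly tuned)."""
    spec = pg.toy_chain_spec(n_trials=4000, seed=7)
    counts, cov = pg.simulate_tuned_population(spec)
    return spec, counts, cov


@pytest.fixture(scope="session")
def common_input_population():
    """Population with common-input noise correlations, no coupling."""
    spec = pg.PopulationSpec(
        n_neurons=12, n_trials=1600, bin_duration=0.2, tuning_kind="cosine",
        common_input_rho=0.3, common_input_gain=0.5, seed=23,
    )
    counts, cov = pg.simulate_tuned_population(spec)
    return spec, counts, cov


@pytest.fixture
def cosine_basis():
    return pg.BasisSpec("cosine_direction")


@pytest.fixture
def direction_table():
    def make(directions):
        return pg.CovariateTable(pd.DataFrame({"direction": np.asarray(directions)}))

    return make
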
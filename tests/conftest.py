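import pytest

import watershed_sem as ws


@pytest.fixture(scope="session")
def truth():
    """Paper-like watershed generating truth on the canonical 20 variables."""
    return ws.default_truth()


@pytest.fixture(scope="session")
def data555(truth):
    """One synthetic cohort at the study's sample size."""
    return ws.simulate_dataset(truth, ws.SimulationConfig(n=555, seed=0))


@pytest.fixture(scope="session")
def moments555(data555):
    return ws.SampleMoments.from_data(data555)


@pytest.fixture(scope="session")
def watershed_fit(moments555):
    return ws.fit_model(ws.build_full_watershed(), moments555)


@pytest.fixture(scope="session")
def population_moments(truth):
    """The truth's exact implied covariance treated as sample moments."""
    return ws.SampleMoments(S=truth.implied, names=truth.names, n=555)
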
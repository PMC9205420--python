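import numpy as np
import pytest

from sistok import evoked_spec, generate_sc_scenarios, simulate_tvmvar


@pytest.fixture(scope="session")
def evoked():
    """Evoked-like simulated dataset: data, ground truth, true edges, spec."""
    spec, edges = evoked_spec(seed=7)
    data, A_true = simulate_tvmvar(spec)
    return data, A_true, edges, spec


@pytest.fixture(scope="session")
def concordant_prior(evoked):
    _, _, edges, spec = evoked
    return generate_sc_scenarios(edges, "concordant", spec.d)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
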
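import pytest

from memcoherence import (
    ModelParams,
    assign_orders,
    make_encoding_schedule,
    make_events,
    make_test_schedule,
    run_simulation,
)


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def protocol():
    """The standard overlapping-pairs protocol: 72 events, both orders."""
    events = make_events(36, 36, seed=11)
    orders = assign_orders(events, "pairs", seed=12)
    enc = make_encoding_schedule(events, "pairs", orders, seed=13)
    test = make_test_schedule(events, seed=14)
    return events, enc, test


@pytest.fixture(scope="session")
def model_responses(protocol, default_params):
    """Full 26-simulation run of the network over the standard protocol."""
    events, enc, test = protocol
    return run_simulation(events, enc, test, default_params, seed=2024)
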
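import pytest

import sizepool as sp


@pytest.fixture(scope="session")
def experiment():
    """One default simulated study, shared read-only across tests."""
    return sp.simulate_experiment(sp.SimConfig(seed=11))


@pytest.fixture(scope="session")
def filtered_table(experiment):
    table, _ = sp.quality_filter(experiment.table)
    return table
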
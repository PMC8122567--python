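import pytest

from splicescreen import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One moderately sized synthetic screen shared across tests."""
    return simulate_dataset(SimulationConfig(n_events=400, seed=11))


@pytest.fixture(scope="session")
def screened(small_dataset):
    """Differential screen results over the shared dataset, with category."""
    import pandas as pd

    from splicescreen import screen_events

    meta = pd.DataFrame(
        {
            "event_id": [e.event_id for e in small_dataset.events],
            "category": [e.category for e in small_dataset.events],
        }
    )
    return screen_events(small_dataset.counts).merge(meta, on="event_id")
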
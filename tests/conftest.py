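import numpy as np
import pandas as pd
import pytest

from cytoabc.config import CDCModelParams, SimulationConfig, SubsetSpec
from cytoabc.events import EventTable


def make_config(**overrides) -> SimulationConfig:
    """A compact two-subset configuration for unit tests."""
    defaults = dict(
        subsets=[
            SubsetSpec("T-bright", "lymphoid", 0.5,
                       {"CD3": "+", "CD19": "-"}, 400_000.0, 50_000.0),
            SubsetSpec("B-dim", "lymphoid", 0.4,
                       {"CD3": "-", "CD19": "+"}, 120_000.0, 30_000.0),
        ],
        n_donors=2,
        events_per_subset=2000,
        cdc=CDCModelParams(),
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults).validate()


@pytest.fixture
def small_config() -> SimulationConfig:
    return make_config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_table(values: dict, metadata: dict | None = None,
               labels=None) -> EventTable:
    return EventTable(pd.DataFrame(values), dict(metadata or {}),
                      labels=None if labels is None else pd.Series(labels))
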
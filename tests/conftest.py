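import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """One seeded synthetic SEM world shared across tests."""
    from soilniche.synthetic import default_config, generate_dataset

    config, spec = default_config(n_samples=800, n_taxa=3, seed=11)
    dataset = generate_dataset(config, spec)
    return config, spec, dataset


@pytest.fixture()
def counts_table():
    from soilniche.io import AbundanceTable

    data = pd.DataFrame(
        {
            "s1": [120, 40, 240, 100],
            "s2": [30, 90, 60, 20],
            "s3": [500, 100, 300, 100],
        },
        index=["otu1", "otu2", "otu3", "otu4"],
    )
    return AbundanceTable(data, mode="counts")
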
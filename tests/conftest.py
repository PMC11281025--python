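import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wetlandrisk import default_registry
from wetlandrisk.registry import METALS

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def toy_samples():
    """Two hand-built samples with easily hand-checked indices."""
    rows = [
        # P_i: Hg 2.0, As 0.05, Cu 0.01, Zn 0.02, Pb 0.1, Cd 0.01
        {"sample_id": "s1", "group": "g", "Hg": 0.10, "As": 2.5, "Cu": 10.0,
         "Zn": 20.0, "Pb": 1.0, "Cd": 0.05},
        # P_i: Hg 8.0, As 0.1, Cu 0.05, Zn 0.1, Pb 0.2, Cd 0.02
        {"sample_id": "s2", "group": "g", "Hg": 0.40, "As": 5.0, "Cu": 50.0,
         "Zn": 100.0, "Pb": 2.0, "Cd": 0.10},
    ]
    return pd.DataFrame(rows, columns=["sample_id", "group"] + list(METALS))


@pytest.fixture()
def rng():
    return np.random.default_rng(20231001)
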
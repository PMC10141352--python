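import numpy as np
import pandas as pd
import pytest

from ctalloc.synth import SynthParams, generate_units, units_to_frame


@pytest.fixture(scope="session")
def units130() -> pd.DataFrame:
    """Default-condition synthetic table: 130 units, fixed seed."""
    return units_to_frame(generate_units(SynthParams(seed=1)))


@pytest.fixture
def small_units() -> pd.DataFrame:
    """Four hand-made units with simple round numbers for hand-checked oracles."""
    return pd.DataFrame({
        "unit_code": ["u1", "u2", "u3", "u4"],
        "unit_name": ["one", "two", "three", "four"],
        "population": [100_000, 200_000, 150_000, 120_000],
        "female_ratio": [0.50, 0.52, 0.54, 0.51],
        "over65": [20_000, 40_000, 30_000, 24_000],
        "under14": [15_000, 30_000, 22_500, 18_000],
        "referred_patients": [5_000, 12_000, 8_000, 6_000],
        "historical_scanners": [2, 5, 3, 2],
        "waiting_days": [10.0, 20.0, 30.0, 40.0],
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
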
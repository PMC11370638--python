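import numpy as np
import pandas as pd
import pytest

from virokin.io import SeriesTable


@pytest.fixture
def small_series_frame() -> pd.DataFrame:
    """A minimal well-formed long-format series table (3 rows)."""
    return pd.DataFrame(
        {
            "time_h": [0.0, 6.0, 12.0],
            "treatment": ["single_A"] * 3,
            "replicate": ["1"] * 3,
            "analyte": ["virus_particles"] * 3,
            "value": [1e6, 1.1e6, 2.5e6],
            "temperature_c": [3.0] * 3,
        }
    )


@pytest.fixture
def small_series_table(small_series_frame) -> SeriesTable:
    return SeriesTable(small_series_frame)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
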
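import numpy as np
import pandas as pd
import pytest

from codkit.hierarchy import toy_hierarchy
from codkit.synthdata import SimConfig


@pytest.fixture(scope="session")
def hier():
    return toy_hierarchy()


@pytest.fixture
def small_config(hier):
    """One well-registered VR location, one year: fast observation tests."""
    return SimConfig(
        n_locations=1,
        year_start=2010,
        year_end=2010,
        hierarchy=hier,
        sdi_start=np.array([0.8]),
        base_population=500_000,
        source_types=np.array(["VR"], dtype=object),
        seed=7,
    )


@pytest.fixture
def stratum_records():
    """A single stratum with two target causes and one garbage code."""
    return pd.DataFrame(
        {
            "location": 0,
            "year": 2010,
            "age": 10,
            "sex": "male",
            "source": "VR",
            "code": ["ncd_0", "ncd_1", "gb_major_1"],
            "deaths": [30.0, 70.0, 10.0],
        }
    )
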
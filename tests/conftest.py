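import numpy as np
import pandas as pd
import pytest

from metaminer import PeakTable, SampleMetadata, SimDesign, simulate_peak_table


@pytest.fixture
def small_table():
    data = pd.DataFrame(
        [[1.0, 10.0, 100.0],
         [2.0, 20.0, 200.0],
         [3.0, 30.0, 300.0],
         [4.0, 40.0, 400.0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["v1", "v2", "v3"],
    )
    return PeakTable(data)


@pytest.fixture
def small_meta():
    frame = pd.DataFrame(
        {"group": ["A", "A", "B", "B"], "injection_order": [1, 2, 3, 4]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SampleMetadata(frame)


@pytest.fixture(scope="session")
def sim_study():
    """A moderate two-group study with planted markers, shared across tests."""
    design = SimDesign(n_per_group=20, n_variables=50, n_informative=5,
                       effect_size=2.0, seed=11)
    return simulate_peak_table(design)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
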
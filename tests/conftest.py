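import numpy as np
import pandas as pd
import pytest

from metabokit.feature_table import FeatureTable
from metabokit.msio import synthesize_run


@pytest.fixture
def clean_run():
    """Noise-free run: one analyte with two MS2 fragments, apex at 60 s."""
    return synthesize_run(
        [(370.1642, 60.0, 1000.0, {328.15: 200.0, 268.13: 150.0})],
        noise_sd=0.0, rt_grid=np.arange(0.0, 120.0, 1.0), seed=1)


@pytest.fixture
def noisy_run():
    return synthesize_run(
        [(370.1642, 60.0, 1000.0, {328.15: 200.0, 268.13: 150.0}),
         (304.1538, 80.0, 500.0, {182.12: 300.0})],
        noise_sd=5.0, rt_grid=np.arange(0.0, 120.0, 1.0), seed=7)


@pytest.fixture
def small_table():
    """4 features x 4 samples with one NA and one zero."""
    values = pd.DataFrame(
        [[1.0, np.nan, 0.0, 4.0],
         [1.0, 2.0, 3.0, 4.0],
         [5.0, 5.0, 5.0, 5.0],
         [2.0, 4.0, 6.0, 8.0]],
        index=["f1", "f2", "f3", "f4"],
        columns=["s1", "s2", "s3", "s4"])
    meta = pd.DataFrame({"group": ["a", "a", "b", "b"],
                         "age": [1.0, 2.0, 3.0, 4.0]},
                        index=["s1", "s2", "s3", "s4"])
    return FeatureTable(values, meta)
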
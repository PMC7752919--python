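import warnings

import numpy as np
import pandas as pd
import pytest

from metacohort.simulate import SimulationConfig, generate_meta_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact 3-dataset cohort with full technical structure."""
    cfg = SimulationConfig(
        n_datasets=3,
        samples_per_dataset=80,
        n_genes=60,
        seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr, clin, annot, truth = generate_meta_cohort(cfg)
    return cfg, expr, clin, annot, truth


@pytest.fixture()
def toy_clinical():
    """Hand-written 10-sample clinical table covering every filter."""
    return pd.DataFrame(
        {
            "dataset_id": ["A"] * 5 + ["B"] * 5,
            "site": ["colon", "rectum", "colon", "rectum", "colon"] * 2,
            "stage": ["I", "II", "III", "IV", "unknown", "I", "IV", "II", "III", "I"],
            "relapse_time": [12.0, 8.0, 30.0, np.nan, np.nan, 5.0, np.nan, 22.0, 14.0, 40.0],
            "relapse_event": [1.0, 0.0, 1.0, np.nan, np.nan, 1.0, np.nan, 0.0, 1.0, 0.0],
            "os_time": [20.0] * 10,
            "os_event": [1, 0, 1, 1, 0, 1, 1, 0, 0, 1],
        },
        index=[f"s{i}" for i in range(10)],
    )
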
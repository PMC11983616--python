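import numpy as np
import pandas as pd
import pytest

from specfuse import synthetic as sy


@pytest.fixture(scope="session")
def small_config():
    """A 48-sample-per-group world (4 per design cell) for fast tests."""
    return sy.SimConfig(n_per_group=48, seed=7)


@pytest.fixture(scope="session")
def small_world(small_config):
    design, physio, spectra = sy.simulate(small_config, seed=7)
    return small_config, design, physio, spectra


@pytest.fixture(scope="session")
def default_world():
    """The full default world (240/group) used by calibration checks."""
    cfg = sy.SimConfig(seed=1)
    design, physio, spectra = sy.simulate(cfg, seed=1)
    return cfg, design, physio, spectra


def group_ids(design: pd.DataFrame, group: str):
    return design.loc[design["group"] == group, "sample_id"].tolist()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
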
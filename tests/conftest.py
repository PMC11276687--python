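import warnings

import numpy as np
import pytest

import grasshab as gh


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down study conditions shared across tests."""
    return gh.SimConfig(nrows=50, ncols=50, n_occurrences=80, seed=3)


@pytest.fixture(scope="session")
def small_stack(small_cfg):
    return gh.generate_env_stack(small_cfg)


@pytest.fixture(scope="session")
def truth():
    return gh.default_truth()


@pytest.fixture(scope="session")
def small_occ(small_stack, truth, small_cfg):
    return gh.sample_occurrences(small_stack, truth, small_cfg)


@pytest.fixture(scope="session")
def small_bg(small_stack):
    return gh.sample_background(small_stack, 2000, seed=1)


@pytest.fixture(scope="session")
def lqh_features(small_stack, small_occ, small_bg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gh.build_features(small_stack, small_occ, small_bg,
                                 fc="LQH", n_knots=10)


@pytest.fixture(scope="session")
def lqh_model(lqh_features):
    return gh.fit(lqh_features, rm=1.0)


@pytest.fixture
def flat_grid():
    return gh.GridSpec(nrows=10, ncols=10, xmin=0.0, ymax=10.0, cell=1.0)


def make_raster(data, cell=1.0, categorical=False, geographic=False):
    data = np.asarray(data, dtype=float)
    grid = gh.GridSpec(nrows=data.shape[0], ncols=data.shape[1], xmin=0.0,
                       ymax=data.shape[0] * cell, cell=cell,
                       geographic=geographic)
    return gh.Raster(data, grid, categorical=categorical)
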
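import warnings

import numpy as np
import pytest

from forestvol.synthetic import LandscapeConfig, simulate

warnings.filterwarnings("ignore", category=RuntimeWarning, module="scipy")


@pytest.fixture(scope="session")
def small_config() -> LandscapeConfig:
    """A 12-plot landscape small enough for the full feature stack in tests.

    Coarser tile pixels than the survey default keep texture extraction
    fast; none of the assertions that use this fixture depend on pixel
    scale or plot count.
    """
    return LandscapeConfig(n_plots=12, domain_size_m=3000.0, pixel_size_m=0.3,
                           seed=42)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def feature_table(small_landscape):
    from forestvol.pipeline import build_feature_table
    return build_feature_table(small_landscape)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
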
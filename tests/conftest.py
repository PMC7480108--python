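import warnings

import numpy as np
import pytest
from hypothesis import settings

from endopolar import SceneConfig, generate_polarity_movie

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(autouse=True)
def _quiet_segmentation_warnings():
    # empty-mask warnings are part of the API; keep test output readable
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*empty mask.*")
        warnings.filterwarnings("ignore", message=".*constant image.*")
        yield


@pytest.fixture(scope="session")
def short_movie():
    """Small single-cell polarity movie shared across tests."""
    cfg = SceneConfig(n_frames=8, seed=11,
                      angular_model=("von_mises", 0.0, 2.0))
    return generate_polarity_movie(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
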
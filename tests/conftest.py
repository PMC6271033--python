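import warnings

import numpy as np
import pytest

from hsiauth.pipeline import RunConfig, run_train
from hsiauth.synthetic import make_study_replica

SMALL = dict(shape=(96, 128), n_bands=96, well_radius=7.0)


@pytest.fixture(scope="session")
def small_replica():
    """Scaled-down study replica: 96x128 pixels, 96 bands, 7-px wells."""
    return make_study_replica(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_trained(small_replica):
    """Trained pipeline on the small replica's calibration scene."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_train(small_replica.calibration_scene, RunConfig(seed=11), output_dir=None)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
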
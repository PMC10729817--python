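import numpy as np
import pytest

from spinsense import phantom as ph


@pytest.fixture(scope="session")
def small_cfg():
    return ph.AcquisitionConfig(duration_s=0.35, noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def ccw_series(small_cfg):
    """One short, noise-free CCW record shared across tests (28 stacks)."""
    motion = ph.MotionModel(direction="ccw", rotation_hz=5.0,
                            initial_position=(8.5, 10.0, 10.0))
    series, gt = ph.generate_stack_series(ph.HeadPhantom(), motion, small_cfg)
    return series, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
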
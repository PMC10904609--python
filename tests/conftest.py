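import numpy as np
import pytest

from hemonet.containers import FINGERS
from hemonet.simulate import (
    NoiseConfig,
    SyntheticConfig,
    build_paradigm,
    simulate_recording,
)


@pytest.fixture(scope="session")
def default_timeline():
    return build_paradigm()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def noiseless_config(n_channels: int = 2, seed: int = 0, **kwargs) -> SyntheticConfig:
    return SyntheticConfig(
        montage_channels=n_channels,
        noise=NoiseConfig(cardiac_amp=0, resp_amp=0, mayer_amp=0, white_sd=0),
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def noiseless_run(default_timeline):
    """One clean 2-channel recording with its ground truth."""
    rec, gt = simulate_recording(default_timeline, noiseless_config())
    return rec, gt


@pytest.fixture(scope="session")
def gaussian_blobs():
    """Well-separated 5-class Gaussian toy set in 8 dimensions."""
    rng = np.random.default_rng(7)
    centers = rng.normal(scale=6.0, size=(5, 8))
    X = np.vstack([c + rng.normal(size=(40, 8)) for c in centers])
    y = np.array([f for f in FINGERS for _ in range(40)])
    return X, y
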
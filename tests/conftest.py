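import numpy as np
import pytest

from conefinder import MosaicParams, NetworkConfig, TrainConfig, train_model
from conefinder.experiment import synthetic_samples


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    """Small network for fast CPU tests: depth 2, 4 base filters, 32 px."""
    return NetworkConfig(depth=2, base_filters=4, kernel=3, in_size=32)


@pytest.fixture(scope="session")
def tiny_mosaic():
    """Mosaic parameters matching the tiny network's 32-px frame."""
    return MosaicParams(size=32, spacing=7.0, jitter=0.5, blob_sigma=1.5,
                        noise_sd=0.03, modality="confocal")


@pytest.fixture(scope="session")
def tiny_trained_model(tiny_net_cfg, tiny_mosaic):
    """A briefly trained tiny model shared across tests."""
    samples = synthetic_samples(12, tiny_mosaic, label_radius=2, seed=77)
    return train_model(tiny_net_cfg, samples, TrainConfig(epochs=6, seed=3)), samples
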
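import numpy as np
import pytest

from cmttrack.segnet import SegModel, TrainConfig, train_source
from cmttrack.simdata import SceneConfig, generate_sequence


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_sequence():
    """A small labelled video shared across tests (8 frames, 5 cells)."""
    cfg = SceneConfig(frame_size=(64, 64), n_cells=5, cell_radius_range=(4, 7),
                      intensity_fg=0.8, intensity_bg=0.2, noise_sigma=0.02,
                      motion_sigma=1.0, n_frames=8, seed=7)
    return generate_sequence(cfg)


@pytest.fixture(scope="session")
def trained_model(tiny_sequence):
    """A segmentation unit briefly trained on the tiny sequence."""
    model = SegModel(base_channels=4, seed=0)
    train_source(model, (tiny_sequence.frames, tiny_sequence.instance_masks),
                 TrainConfig(epochs=6, learning_rate=3e-3, batch_size=4, seed=0))
    return model
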
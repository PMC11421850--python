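import numpy as np
import pytest

from hypometrics import synthio


@pytest.fixture(scope="session")
def heart_video_60():
    """Noise-free 60 bpm, 10 s heart video with its truth."""
    return synthio.gen_heart_video(bpm=60.0, duration=10.0, frame_interval=0.1, seed=0)


@pytest.fixture(scope="session")
def cell_images_3():
    """Three cells with known ratios, noise-free."""
    return synthio.gen_cell_images(
        n_cells=3, true_ratios=[1.0, 1.5, 2.0], image_size=160, noise_sd=0.0, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
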
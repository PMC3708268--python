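import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lungcad.phantom import PhantomConfig, apply_degradation, generate_slice
from lungcad.preprocess import motion_blur


@pytest.fixture(scope="session")
def clean_phantom():
    """Standard noise-free 128² phantom with 3 nodules."""
    cfg = PhantomConfig(n_nodules=3, seed=1)
    image, gt = generate_slice(cfg)
    return cfg, image, gt


@pytest.fixture(scope="session")
def degraded_pair(clean_phantom):
    """The standard blurred+noisy phantom (blur 7 px, σ = 0.02)."""
    cfg, image, _gt = clean_phantom
    blur = motion_blur(image.shape, 7, 0.0)
    degraded = apply_degradation(image, blur, noise_sigma=0.02, seed=5)
    return image, degraded, blur


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
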
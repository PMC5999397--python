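import numpy as np
import pytest

from icescreen import phantom

#: compact volume used by most unit tests (nm: 128 x 153.6 x 153.6)
SMALL_SHAPE = (160, 192, 192)


def small_config(**kw):
    # the smaller field holds the default conditions' layer *saturation*
    # (not the particle count), so packing and locator behaviour match
    kw.setdefault("volume_shape", SMALL_SHAPE)
    kw.setdefault("n_particles", 100)
    return phantom.PhantomConfig(**kw)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default survey-like conditions at particle SNR ~ 3."""
    cfg = small_config(noise_sigma=0.233, seed=3)
    vol, gt = phantom.make_phantom(cfg)
    return cfg, vol, gt


@pytest.fixture(scope="session")
def noiseless_phantom():
    cfg = small_config(n_particles=0, noise_sigma=0.0, seed=1)
    vol, gt = phantom.make_phantom(cfg)
    return cfg, vol, gt


@pytest.fixture(scope="session")
def grid_xy():
    xs = (np.arange(SMALL_SHAPE[2]) + 0.5) * 0.8
    ys = (np.arange(SMALL_SHAPE[1]) + 0.5) * 0.8
    X, Y = np.meshgrid(xs, ys)
    cx, cy = xs.mean(), ys.mean()
    return xs, ys, X, Y, cx, cy


@pytest.fixture(scope="session")
def hole_mask(grid_xy):
    _, _, X, Y, cx, cy = grid_xy
    return np.hypot(X - cx, Y - cy) < 90.0
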
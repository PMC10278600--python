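import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from pamp.simulate import SimConfig, simulate_movie


@pytest.fixture(scope="session")
def small_movie():
    """Five-cell, 30-frame noise-bearing movie shared by chain tests."""
    cfg = SimConfig(n_cells=5, field_size=(256, 256), n_frames=30, seed=3)
    movie, gt = simulate_movie(cfg)
    return cfg, movie, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def disc_mask(radius_px: int, pad: int = 3) -> np.ndarray:
    """Digitised disc: pixels whose centre lies inside the radius."""
    n = 2 * radius_px + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px ** 2
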
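import numpy as np
import pytest

from patchstoich import RunConfig


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def gaussian_spot_frame(shape, x0, y0, total, sigma_px, background=0.0):
    """Pixel-integrated Gaussian spot on a constant background (test helper,
    written independently of the package's renderer)."""
    from scipy.special import erf

    h, w = shape
    s = sigma_px * np.sqrt(2.0)
    xs = np.arange(w)
    ys = np.arange(h)
    fx = 0.5 * (erf((xs + 0.5 - x0) / s) - erf((xs - 0.5 - x0) / s))
    fy = 0.5 * (erf((ys + 0.5 - y0) / s) - erf((ys - 0.5 - y0) / s))
    return background + total * fy[:, None] * fx[None, :]
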
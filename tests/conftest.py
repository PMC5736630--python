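import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import microrheo as mr

settings.register_profile(
    "deterministic", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def snr10_movie():
    """A rendered SNR-10 Brownian movie with its ground truth (shared)."""
    cfg = mr.SimConfig(model="brownian", n_particles=36, n_frames=150, fps=60.0,
                       box_size=25.6, init="grid", seed=5,
                       model_params={"D": 0.15})
    truth = mr.simulate(cfg)
    stack = mr.render_video(truth, psf_sigma=1.5, peak_intensity=6000,
                            background_level=800, noise_sigma=600,
                            image_shape=(256, 256), pixel_size=0.1, seed=5)
    return truth, stack


def gaussian_spot(shape, cx, cy, sigma=1.5, amplitude=1000.0, background=0.0,
                  aspect=1.0):
    """Render one analytic Gaussian spot (x = column, y = row)."""
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    sx, sy = sigma * aspect, sigma
    return background + amplitude * np.exp(
        -((xx - cx) ** 2 / (2 * sx ** 2) + (yy - cy) ** 2 / (2 * sy ** 2)))
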
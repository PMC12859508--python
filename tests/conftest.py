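import numpy as np
import pytest

from flickerspec import localize, simulate
from flickerspec.boundary import ContourCurve, uniform_angles


@pytest.fixture()
def sim_params():
    """sigma_bar = 300, kappa = 5 kBT, R = 2 um at 0.1 um/px (R = 20 px)."""
    return simulate.SimulationParams.from_sigma_bar(300.0, 5.0, 2.0, pixel_size=0.1)


@pytest.fixture()
def imaging_config():
    return localize.ImagingConfig(min_intensity=0.3, min_size=25, max_size=55)


def circle_contour(radius_px: float, center=(0.0, 0.0), n_angles: int = 400) -> ContourCurve:
    angles = uniform_angles(n_angles)
    return ContourCurve(angles, np.full(n_angles, float(radius_px)), center)


def render_circle(radius_px: float, params: simulate.SimulationParams, frame=(96, 96), center=(48.0, 48.0), seed=None):
    """Noiseless unless params.noise_sd > 0 and a seed is given."""
    contour = circle_contour(radius_px, center)
    return simulate.render_frame(contour, params, frame, center, seed=seed)


@pytest.fixture(scope="session")
def droplet_video():
    """30-frame, 1-droplet rendered video (R = 20 px) with ground truth."""
    params = simulate.SimulationParams.from_sigma_bar(300.0, 5.0, 2.0, pixel_size=0.1)
    frames, truth = simulate.generate_video(params, 30, 1, seed=123)
    return frames, truth, params


@pytest.fixture(scope="session")
def two_droplet_video():
    """20-frame video with two droplets 60 px apart."""
    params = simulate.SimulationParams.from_sigma_bar(300.0, 5.0, 2.0, pixel_size=0.1)
    centers = [(40.0, 48.0), (100.0, 48.0)]
    frames, truth = simulate.generate_video(
        params, 20, 2, seed=321, centers=centers, frame_shape=(96, 140)
    )
    return frames, truth, params
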
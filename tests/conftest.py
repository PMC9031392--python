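import numpy as np
import pytest

from phbdeg.images import ImageSeries
from phbdeg.synthetic import SceneParams, logistic_trajectory, simulate_image_series


@pytest.fixture(scope="session")
def small_noiseless_sim():
    """A small rendered series with no noise, no illumination, no mycelium.

    Under these conditions any threshold strictly between the agar and
    grain grey levels must recover the truth masks exactly.
    """
    params = SceneParams(
        image_size=(128, 128),
        n_grains=12,
        grain_radius_range=(3.0, 6.0),
        noise_sd=0.0,
        illumination_gradient=0.0,
        mycelium_growth_rate=0.0,
        seed=7,
    )
    traj = logistic_trajectory(np.linspace(0.0, 336.0, 8), t50=150.0)
    return simulate_image_series(params, traj)


@pytest.fixture(scope="session")
def default_sim():
    """A full-noise series with growing mycelium, default intensities."""
    params = SceneParams(image_size=(256, 256), n_grains=20, seed=11)
    traj = logistic_trajectory(np.linspace(0.0, 336.0, 10), t50=150.0)
    return simulate_image_series(params, traj)


def make_series(frames, times=None, **kwargs):
    frames = [np.asarray(f, dtype=float) for f in frames]
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return ImageSeries(frames=frames, times=times, **kwargs)
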
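import numpy as np
import pytest

from gcxquant import GcxiConfig, IntensityProfile, VesselScene


NO_SMOOTHING = GcxiConfig(smoothing_window=1, derivative_window=1)


def gaussian_profile(sigma=10.0, amplitude=100.0, background=0.0,
                     step=0.1, extent=5.0, center=0.0, pixel_scale=1.0):
    """Analytic Gaussian ridge profile sampled at a uniform step."""
    half = extent * sigma
    x = np.arange(-half, half + step / 2, step) + center
    y = background + amplitude * np.exp(-((x - center) ** 2) / (2 * sigma**2))
    return IntensityProfile(positions=x, intensities=y, pixel_scale=pixel_scale)


def raised_cosine_profile(w=20.0, amplitude=100.0, background=0.0, step=0.1):
    x = np.arange(-2.0 * w, 2.0 * w + step / 2, step)
    y = np.where(np.abs(x) <= w, amplitude * 0.5 * (1 + np.cos(np.pi * x / w)), 0.0)
    return IntensityProfile(positions=x, intensities=y + background)


@pytest.fixture
def no_smoothing():
    return NO_SMOOTHING


@pytest.fixture
def small_scene():
    """A 40-um vessel in a 384-px frame at 0.25 um/px."""
    return VesselScene(
        height_px=384,
        width_px=384,
        pixel_scale=0.25,
        centerline=((192.0, 10.0), (192.0, 374.0)),
        inner_diameter_um=40.0,
        wall_sigma_um=4.0,
    )
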
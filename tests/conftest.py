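import numpy as np
import pytest

from phasorflim import default_metadata
from phasorflim.synthetic import default_scene, expected_cube, render_scene


@pytest.fixture(scope="session")
def meta256():
    return default_metadata(n_time_bins=256)


@pytest.fixture(scope="session")
def meta1024():
    return default_metadata(n_time_bins=1024)


@pytest.fixture(scope="session")
def meta4096():
    return default_metadata(n_time_bins=4096)


@pytest.fixture(scope="session")
def scene_spec():
    """Small paper-like scene used across modules (session-cached)."""
    return default_scene(shape=(64, 64), photons_per_pixel=1e4, seed=7)


@pytest.fixture(scope="session")
def rendered_scene(scene_spec):
    return render_scene(scene_spec)


@pytest.fixture(scope="session")
def noiseless_scene(scene_spec):
    """Expected (noise-free) cube + truth for pixel-exact assertions."""
    return expected_cube(scene_spec)


def numeric_phasor(profile_t, t_grid, omega):
    """Independent phasor oracle: trapezoidal integration of a continuous
    profile sampled on a fine time grid (no binning path shared with the
    implementation)."""
    intensity = np.trapezoid(profile_t, t_grid)
    g = np.trapezoid(profile_t * np.cos(omega * t_grid), t_grid) / intensity
    s = np.trapezoid(profile_t * np.sin(omega * t_grid), t_grid) / intensity
    return g, s
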
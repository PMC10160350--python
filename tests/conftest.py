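import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zoobooth.detection import SpeciesProfile
from zoobooth.synthetic import SceneConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230420)


@pytest.fixture
def daphnia_profile():
    return SpeciesProfile(
        name="daphnia",
        min_area_px=1500,
        max_area_px=4000,
        min_lw_ratio=1.2,
        max_lw_ratio=1.7,
        min_brightness=30,
        min_sharpness=1.8,
        min_edge_distance_px=10,
        optimal_percentile=93,
    )


@pytest.fixture
def analogue_profile():
    """Daphnia-style profile with area bounds spanning the synthetic
    0.8-4.0 mm size range at 0.02 mm/px."""
    return SpeciesProfile(
        name="daphnia_analogue",
        min_area_px=200,
        max_area_px=40000,
        min_lw_ratio=1.1,
        max_lw_ratio=1.8,
        min_brightness=30,
        min_sharpness=1.8,
        min_edge_distance_px=10,
        optimal_percentile=93,
    )


@pytest.fixture
def small_scene():
    """Compact scene geometry that keeps unit tests fast."""
    return SceneConfig(
        frame_size=(840, 600),
        crop_box=(70, 50, 700, 500),
        n_frames=150,
        semi_major_px=60.0,
        semi_minor_px=42.0,
        mm_per_pixel=0.02,
        seed=7,
    )
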
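import numpy as np
import pytest

from valguscv import LandmarkTriple, SceneSpec, render_scene


@pytest.fixture
def simple_triple() -> LandmarkTriple:
    return LandmarkTriple(asis_xy=(400.0, 200.0), patella_xy=(420.0, 660.0), att_xy=(460.0, 1000.0))


@pytest.fixture
def clean_scene(simple_triple):
    """Noise-free 800x1200 scene with three red radius-9 discs."""
    spec = SceneSpec(landmarks_truth=simple_triple, marker_radius_px=9.0, seed=0)
    frame, truth = render_scene(spec)
    return spec, frame, truth


def disc_mask(shape: tuple[int, int], center_xy, radius: float) -> np.ndarray:
    """Independent boolean mask of a rendered disc (coverage > 0.5 edge model)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(xx - center_xy[0], yy - center_xy[1]) <= radius
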